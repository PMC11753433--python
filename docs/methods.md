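# Model and methods

## The cell model

`dlgnsim` implements a two-compartment conductance-based model of a dorsal
lateral geniculate nucleus (dLGN) thalamocortical relay neuron: a
somato-dendritic compartment and an axonal (axon-initial-segment)
compartment coupled by a fixed ohmic conductance.  Compartments are treated
as isopotential; membrane area is absorbed into the compartment capacitances
(pF) and into absolute maximal conductances (nS), so no specific-density
bookkeeping is needed.

Membrane equation per compartment (units: mV, ms, pA, pF, nS):

    C_s dV_s/dt = I_inj(t) - Σ_k I_k(V_s) - g_c (V_s - V_a)
    C_a dV_a/dt =          - Σ_k I_k(V_a) + g_c (V_s - V_a)

Every ionic current follows the Hodgkin–Huxley form

    I = g_max m^p h^q (V - E_rev),        positive = outward,

with first-order gates relaxing to Boltzmann steady states
x_inf(V) = 1/(1 + exp(-(V - V_half)/k)) with bell-shaped voltage-dependent
time constants

    tau(V) = tau_min + tau_amp / (exp((V-v_mid)/s_r) + exp(-(V-v_mid)/s_f)),

Q10-scaled as tau * q10^((t_ref - T)/10).  All kinetics are stated at
t_ref = 30 °C — the temperature of the recordings the model emulates — so
the default simulation applies no rescaling; setting q10 = 1 makes the model
temperature-invariant by construction.

### Channel inventory and localization

| current | gates (p, q) | compartments | role |
|---|---|---|---|
| Na   | m³h | soma + axon | spike upstroke |
| Kdr  | n⁴  | soma + axon | repolarization |
| A    | a⁴b | soma only   | subthreshold outward, rate throttling |
| Kv1 (D-type) | m·h | soma + axon | first-spike delay, rheobase, adaptation |
| T (Cav3) | m²h | soma only | low-threshold Ca burst from hyperpolarized V |
| H (HCN) | one decreasing gate | soma only | resting potential, sag |
| leak | — | soma + axon | resting conductance |

The kinetics are classic thalamocortical relay-cell schemes re-expressed in
the canonical Boltzmann/bell form above, with the D-type Kv1 current added:
low activation threshold (half-activation −41 mV), fast-ish activation
(τ ≈ 5–15 ms) and slow, partial inactivation (τ ≈ 500 ms, shallow
inactivation curve).  The D-current is what makes the model's excitability
phenotype: it delays the first spike ("ramp-and-delay"), raises the
rheobase, and its slow inactivation lets the cell escape late in a long
depolarizing step.

Two gating conventions worth noting:

* Gate slopes are signed: activation gates have k > 0 (x_inf increasing in
  V), inactivation gates k < 0.  The hyperpolarization-activated HCN current
  is represented by an inactivation-type (decreasing) gate, which keeps the
  model-wide contract "activation curves increase, inactivation curves
  decrease" intact.
* The T-type current uses a fixed +120 mV reversal rather than a
  constant-field flux expression: the model carries no intracellular calcium
  state, and a fixed reversal keeps it closed.  No calcium-activated or
  L-type currents are included — the biochemical induction cascade is out of
  the model's scope, and plasticity enters only as static conductance
  changes (below).

### Integration

Exponential Euler on the gates, forward Euler on the voltages, fixed step
dt = 0.025 ms.  Exponential Euler keeps every gate inside [0, 1] whenever
x_inf is, which is why gate-bound violations cannot arise from integration.
Convergence is asserted by step-halving (dt vs dt/2 below 0.5 mV on
subthreshold segments); states leaving a ±500 mV guard band abort with the
first offending time step.  Identical (parameters, protocol, dt) produce
bit-identical traces.

Before t = 0 of any protocol the model is settled for 2 s (3 s for
steady-state reads) at the protocol's holding bias, starting from gate
steady states; settled states are cached by parameter hash.  The batched
kernel integrates many parameter sets (an f-I scan, a DE population) in one
call, which is what keeps rheobase searches and fitting desk-scale.

## Calibrated reference cell

The shipped `data/reference_cell.yaml` is the package's "open-eye control"
cell.  Its defining constraints, all verified by the test suite at run
time:

* resting potential −76 mV at 0 pA; −69 mV under a +13 pA continuous bias
  (chord input resistance ≈ 7 mV / 13 pA ≈ 0.54 GΩ);
* a 47-pA, 800-ms step from rest evokes exactly 3 APs at the control Kv1
  conductance (41.7 nS soma / 23 nS axon) and exactly 10 APs with gKv1 = 0;
* quiescent (non-oscillating) at both holding potentials; low-threshold
  burst on rebound from hyperpolarized potentials; tonic firing when
  depolarized.

The 47-pA comparison is run from the 0-pA (−76 mV) holding regime; the
depolarized (−69 mV / +13 pA) regime is used for the paired-trace
illustration only.  Leak conductance and leak reversal were solved (by
bracketed root-finding on the settled model) so the resting and holding
constraints hold exactly; the remaining conductances were selected on a
grid so the spike-count constraints and the condition ordering (below) hold
with margin, and the spike counts are stable under step halving of dt.
Half-activations and time constants are exposed per channel in the YAML,
so the calibration stage owns every constant.

Two calibration outcomes worth flagging.  The membrane time constant is
long (C ≈ 156 pF total against ~1.9 nS resting conductance): with the
~0.54 GΩ input resistance pinned by the holding constraints, the slow
near-threshold charging that produces the ~12-Hz dendrotoxin-condition
firing requires a correspondingly large capacitance.  And the control
cell's tonic-firing onset sits near −53 mV, which means the depolarized
"transmission-mode" holding of −56 mV cannot be maintained without
spontaneous firing in this parameter set; excitability comparisons use the
−65 mV regime instead.

## In-silico experiments

Four conditions, all static conductance edits of the reference cell:

* control — reference values (gKv1 41.7 / 23 nS);
* deprived — monocular-deprivation analogue, gKv1 = 101.7 / 83 nS;
* dtx — dendrotoxin analogue, gKv1 = 0 / 0;
* ltpie — intrinsic-potentiation analogue, gKv1 halved (20.85 / 11.5 nS);
* tta_p2 — T-type blocker analogue, gT = 0.

No kinetic model of the PKA/Ca cascade is attempted (none is quantified in
the source experiments); LTP-IE is represented solely by the halved Kv1
conductance.  Pharmacology enters only as conductance manipulations.

The induction-protocol generator reproduces the stimulation arithmetic:
trains of 15 brief (2–5 ms) suprathreshold pulses at 40 Hz, one train per
10 s, for 10 min — 900 pulses; frequency changes within-train spacing, not
the count.

The dendrotoxin-subtraction protocol is reproduced in voltage clamp: the
cell is stepped from −80 mV into the −50/−45 mV range with Kv1 intact and
with gKv1 = 0, and the steady clamp currents are subtracted; the T-type
current is disabled during this protocol, as in the recordings it mirrors.
Voltage clamp defaults to whole-cell space clamp (both compartments follow
the command — the AIS of these small cells is electrotonically compact),
which makes the subtraction current exactly linear in gKv1 and equal to
the analytic Kv1 channel current at the clamped voltage.  A soma-only
clamp mode (``space_clamp=False``) is available; with it the axonal
compartment integrates freely and, in the gKv1 = 0 condition, fires escape
spikes — physiologically plausible, but useless for the subtraction
measurement, which is why it is not the default.

## Measurement definitions

* **Spike detection**: upward crossings of 0 mV with a 2-ms refractory
  merge.  The detection level is not the AP threshold.
* **AP threshold**: phase-plot definition — the voltage at the last sample
  before dV/dt first exceeds 20 mV/ms on the upstroke (criterion exposed;
  the source analysis does not state its value).
* **Rheobase**: smallest current on a 10-pA grid (800-ms steps) evoking at
  least one AP, scanned upward from one increment to a 500-pA cap; the
  holding potential (−65 mV in the standard comparison) is set by a
  bracketed holding-current search.  No spiking at the cap is an explicit
  undefined result; a cell that fires spontaneously at the holding
  potential itself (the dendrotoxin condition at −65 mV) reports rheobase
  0 pA — no additional current is needed.
* **Input resistance**: −20 pA / 250 ms pulse; steady deflection averaged
  over the last 50 ms, divided by the current.  Spikes during the pulse
  invalidate the measurement.
* **ISI adaptation**: ISI2 − ISI1 (ms); negative = accelerating discharge.
* **First-spike latency**: from stimulus onset (onset, not pulse midpoint,
  is the assumed reference).  With burst-skipping on, spikes chained by
  ISIs < 20 ms starting at the first spike count as the initial
  low-threshold burst and the first spike after that chain is timed; if no
  initial burst is present the leading spike is treated as the initial
  event.  The 20-ms cut separates burst ISIs (a few ms) from tonic ISIs
  (tens of ms).
* **Jitter**: standard error of first-spike latencies across repeated
  identical (noisy) sweeps.
* **Excitability change**: 100 × mean(after)/mean(before) spike counts,
  ratio of window means per sweep series.

## Calibration by differential evolution

`fit_de` minimises Σ w_i ((f_i − target_i)/tol_i)² over box-bounded
conductances and half-activations with the rand/1/bin DE strategy (F = 0.8,
CR = 0.9, population 40, ≤ 100 generations by default).  The optimizer
backend is `scipy.optimize.differential_evolution` with a vectorised
objective: one DE generation is a single batched simulation of the whole
population.  Failed simulations and undefined features receive a fixed 10⁶
penalty; the best-cost record is non-increasing (elitism) and runs are
reproducible given the seed.  The default recovery task — re-estimating the
somatic Kv1 conductance from noise-free features (AP count, post-burst
latency, resting potential) of the reference cell — recovers 41.7 nS well
within 15 %.

## Synthetic recordings

`surrogate.generate_surrogate` adds iid Gaussian noise (default SD 0.2 mV)
to simulated sweeps; `fixture_suite` writes the canonical test set
(condition × current grids, Rin pulses, voltage-clamp families) with a
ground-truth manifest.  What the surrogates emulate: sampling, additive
recording noise, repeat-to-repeat latency jitter.  What they do not:
electrode/bridge artefacts, series-resistance filtering, cell-to-cell
variability, slow drift.  Tests passing on surrogates therefore validate
the measurement code and parameter-recovery machinery, not the model's
fidelity to any particular biological cell.

## Problem sizes and numerical choices

Simulated durations are what the protocols dictate (0.8–3 s at
dt = 0.025 ms); steady-state reads settle 3–5 s of model time.  The
reference fit and recovery tests use population 40 and tens of
generations.  Holding-current search brackets ±200 pA and bisects to
0.1 mV.  Tie-breaks and degenerate inputs are explicit: zero-volume DE
bounds return the single point; rheobase below the first increment reports
the increment; undefined measurements are `None`, never silent numbers.

## Known limitations

* Two compartments only; no dendritic cable, no synapses (the 40-Hz
  induction is represented as somatic current pulses).
* No calcium dynamics; T-type driving force is ohmic with a fixed reversal.
* The plasticity conditions are static conductance states, so the package
  cannot address induction kinetics, only expression-level excitability.
* Kinetic constants are literature-style schemes calibrated to the
  constraint set above, not fits to raw experimental traces (none are
  available); conclusions about real dLGN neurons should rest on the
  directional/ordering properties, which are robust, not on exact spike
  times.
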