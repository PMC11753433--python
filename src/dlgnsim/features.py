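"""Intrinsic-excitability metrics computed identically from simulated or
imported voltage traces.

The definitions mirror standard current-clamp analysis of thalamic relay
cells: spikes are upward threshold crossings; the AP *threshold* (a distinct
concept from the detection level) is read from the phase plot as the voltage
where dV/dt first exceeds a slope criterion; the rheobase is the smallest
step on a fixed current grid that evokes at least one spike; the input
resistance comes from a small hyperpolarizing pulse; early adaptation is the
difference between the second and first interspike intervals; and the
first-spike latency may skip the initial low-threshold (T-type) burst, which
is separated from tonic firing by an ISI cut-off.

Undefined measurements (no spike, too few spikes, spiking during an Rin
pulse) are returned as ``None`` rather than raised, so batch feature tables
can carry explicit missing values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .cell import CellParameters, StimulusProtocol, Trace, simulate_current_clamp_batch

__all__ = [
    "FeatureVector",
    "detect_spikes",
    "spike_threshold",
    "rheobase",
    "input_resistance",
    "isi_adaptation",
    "first_spike_latency",
    "jitter",
    "excitability_change",
]

#: spike detection level (mV) and refractory separation (ms)
DETECT_V = 0.0
REFRACTORY_MS = 2.0
#: phase-plot slope criterion for the AP threshold (mV/ms)
DVDT_CRITERION = 20.0
#: ISIs shorter than this belong to the initial burst (ms)
BURST_ISI_CUT = 20.0
#: rheobase search values beyond this are reported as undefined (pA)
RHEOBASE_CAP = 500.0


@dataclass
class FeatureVector:
    """Extracted excitability metrics; ``None`` marks undefined entries."""

    ap_count: int | None = None
    ap_amplitude: float | None = None  # mV, peak relative to threshold
    rheobase: float | None = None  # pA
    input_resistance: float | None = None  # MOhm
    resting_v: float | None = None  # mV
    first_spike_latency: float | None = None  # ms
    latency_after_burst: float | None = None  # ms
    isi_diff: float | None = None  # ms, ISI2 - ISI1 (negative = accelerating)
    threshold_v: float | None = None  # mV
    jitter_se: float | None = None  # ms
    excitability_pct: float | None = None  # % of control spike number

    def as_dict(self) -> dict:
        return asdict(self)


def detect_spikes(
    trace: Trace,
    detect_v: float = DETECT_V,
    refractory: float = REFRACTORY_MS,
) -> np.ndarray:
    """Spike times (ms): upward crossings of ``detect_v`` on the somatic
    voltage, merged within a refractory window.  Strictly increasing; may be
    empty."""
    v = np.asarray(trace.v_soma)
    up = np.flatnonzero((v[1:] >= detect_v) & (v[:-1] < detect_v))
    times = trace.t[up + 1]
    if len(times) == 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory:
            kept.append(t)
    return np.asarray(kept)


def spike_threshold(
    trace: Trace,
    spike_time: float,
    dvdt_criterion: float = DVDT_CRITERION,
    window_ms: float = 10.0,
) -> float:
    """AP threshold (mV): phase-plot definition.

    Walking back from the spike peak, the threshold is the voltage at the
    last sample before dV/dt first exceeded ``dvdt_criterion`` (mV/ms) on the
    upstroke.  Raises ``ValueError`` for a malformed spike whose upstroke
    never reaches the criterion.
    """
    v = np.asarray(trace.v_soma)
    dt = trace.dt
    i_spk = int(np.searchsorted(trace.t, spike_time))
    i0 = max(i_spk - int(round(window_ms / dt)), 1)
    i1 = min(i_spk + int(round(window_ms / dt)), len(v) - 1)
    seg = v[i0:i1]
    i_peak = i0 + int(np.argmax(seg))
    dvdt = np.diff(v) / dt  # dvdt[i] = slope between i and i+1
    above = np.flatnonzero(dvdt[i0:i_peak] > dvdt_criterion)
    if len(above) == 0:
        raise ValueError(
            f"no dV/dt > {dvdt_criterion} mV/ms upstroke before spike at "
            f"{spike_time} ms (malformed spike)"
        )
    return float(v[i0 + above[0]])


def rheobase(
    params: CellParameters,
    holding_v: float,
    step_duration: float = 800.0,
    increment: float = 10.0,
    cap: float = RHEOBASE_CAP,
    dt: float = 0.025,
) -> float | None:
    """Smallest step current (pA) on the ``increment`` grid evoking >= 1 AP.

    Steps are applied from the bias current that holds the cell at
    ``holding_v``; returns ``None`` if no current up to ``cap`` spikes, and
    0.0 if the cell already fires spontaneously at the holding potential
    (no additional current is needed to evoke a spike).
    """
    from .cell import ProtocolError, find_holding_current

    if increment <= 0:
        raise ValueError("increment must be positive")
    try:
        bias = find_holding_current(params, holding_v)
    except ProtocolError:
        return 0.0
    amps = np.arange(increment, cap + increment / 2, increment)
    proto = StimulusProtocol(
        "current_clamp",
        [(100.0, 0.0), (step_duration, 1.0), (100.0, 0.0)],
        holding_bias=bias,
        dt=dt,
    )
    traces = simulate_current_clamp_batch([params] * len(amps), proto, scale=amps)
    for amp, tr in zip(amps, traces):
        if len(detect_spikes(tr)) > 0:
            return float(amp)
    return None


def input_resistance(trace: Trace, pulse_onset: float, pulse_duration: float,
                     pulse_pa: float, average_ms: float = 50.0) -> float | None:
    """Input resistance (MOhm) from a small negative current pulse.

    Steady-state voltage deflection (mean over the last ``average_ms`` of the
    pulse) relative to the pre-pulse baseline, divided by the pulse current.
    Returns ``None`` if spikes occur during the pulse (measurement invalid).
    1 mV / 1 pA = 1 GOhm = 1000 MOhm.
    """
    if pulse_pa == 0:
        raise ValueError("pulse current must be nonzero")
    t = trace.t
    base_mask = (t >= max(pulse_onset - average_ms, 0)) & (t < pulse_onset)
    end = pulse_onset + pulse_duration
    ss_mask = (t >= end - average_ms) & (t < end)
    if not base_mask.any() or not ss_mask.any():
        raise ValueError("pulse window outside trace")
    spikes = detect_spikes(trace)
    if any(pulse_onset <= s <= end for s in spikes):
        return None
    dv = float(np.mean(trace.v_soma[ss_mask]) - np.mean(trace.v_soma[base_mask]))
    return dv / pulse_pa * 1000.0


def isi_adaptation(spike_times) -> float | None:
    """ISI2 - ISI1 in ms; negative values mean the train accelerates.

    Undefined (``None``) with fewer than three spikes.
    """
    st = np.asarray(spike_times, dtype=float)
    if len(st) < 3:
        return None
    isi = np.diff(st)
    return float(isi[1] - isi[0])


def first_spike_latency(
    trace: Trace,
    stim_onset: float,
    skip_initial_burst: bool = False,
    burst_isi_cut: float = BURST_ISI_CUT,
) -> float | None:
    """Latency (ms) from stimulus onset to the first qualifying spike.

    With ``skip_initial_burst``, spikes chained by ISIs below
    ``burst_isi_cut`` starting at the first spike count as the initial
    low-threshold burst, and the latency of the first spike after that burst
    is returned.  ``None`` when no qualifying spike exists.
    """
    spikes = detect_spikes(trace)
    spikes = spikes[spikes >= stim_onset]
    if len(spikes) == 0:
        return None
    if not skip_initial_burst:
        return float(spikes[0] - stim_onset)
    i = 0
    while i + 1 < len(spikes) and spikes[i + 1] - spikes[i] < burst_isi_cut:
        i += 1
    if i + 1 >= len(spikes):
        return None  # the burst was the whole response
    return float(spikes[i + 1] - stim_onset)


def jitter(latencies) -> float:
    """Standard error of the first-spike latency across repeats (ms)."""
    lat = np.asarray(latencies, dtype=float)
    if len(lat) < 2:
        raise ValueError("jitter needs at least two repeats")
    return float(np.std(lat, ddof=1) / math.sqrt(len(lat)))


def excitability_change(before_counts, after_counts) -> float | None:
    """Spike number after induction as % of the pre-induction window mean."""
    b = np.asarray(before_counts, dtype=float)
    a = np.asarray(after_counts, dtype=float)
    if len(b) == 0 or len(a) == 0:
        raise ValueError("both windows must be non-empty")
    if b.mean() == 0:
        return None
    return float(100.0 * a.mean() / b.mean())


def ap_amplitude(trace: Trace, spike_time: float,
                 dvdt_criterion: float = DVDT_CRITERION) -> float:
    """Spike height (mV) from phase-plot threshold to peak."""
    thr = spike_threshold(trace, spike_time, dvdt_criterion)
    dt = trace.dt
    i_spk = int(np.searchsorted(trace.t, spike_time))
    i1 = min(i_spk + int(round(10.0 / dt)), len(trace.v_soma))
    return float(np.max(trace.v_soma[i_spk:i1]) - thr)
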