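"""Feature-based model calibration by differential evolution.

Free parameters (maximal conductances in nS, gate half-activations in mV)
are fitted so that features extracted from simulated protocols match a
target table, minimising

    cost = sum_i  w_i * ((f_i - target_i) / tol_i)**2

where the per-feature tolerance doubles as the residual scale.  A candidate
whose simulation fails, or that leaves a target feature undefined (e.g. no
spike where a latency is requested), receives a fixed penalty so the
optimizer can keep moving.

The optimizer is the rand/1/bin differential-evolution strategy (F = 0.8,
CR = 0.9), run through :func:`scipy.optimize.differential_evolution` with a
vectorised objective: a whole DE population is integrated as one batched
kernel call, which is what makes desk-scale fitting fast.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import differential_evolution

from . import features as feat
from .cell import (CellParameters, IntegrationError, StimulusProtocol,
                   simulate_current_clamp_batch)

__all__ = [
    "FeatureTarget",
    "ParameterBounds",
    "FitResult",
    "feature_cost",
    "fit_de",
]

#: cost assigned to failed simulations / undefined target features
PENALTY = 1.0e6

#: features the cost function knows how to extract from one step protocol
_KNOWN_FEATURES = (
    "ap_count", "resting_v", "steady_v", "first_spike_latency",
    "latency_after_burst", "ap_amplitude", "isi_diff",
)


@dataclass(frozen=True)
class FeatureTarget:
    """One fitted feature: its protocol, target value, weight and scale."""

    feature: str
    protocol: StimulusProtocol
    target: float
    weight: float = 1.0
    tolerance: float = 1.0
    stim_onset: float = 0.0  # ms, for latency features

    def __post_init__(self) -> None:
        if self.feature not in _KNOWN_FEATURES:
            raise ValueError(f"unknown feature {self.feature!r}")
        if self.weight <= 0 or self.tolerance <= 0:
            raise ValueError("weight and tolerance must be positive")


@dataclass(frozen=True)
class ParameterBounds:
    """Box bounds for the fitted parameters.

    Each name is either ``g:<channel>:<soma|axon>`` (nS) or
    ``vhalf:<channel>:<act|inact>`` (mV).
    """

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"bound {name}: lower > upper")
            if name.startswith("g:") and lo < 0:
                raise ValueError(f"bound {name}: conductances cannot be negative")

    @property
    def names(self) -> list[str]:
        return list(self.bounds)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.bounds[n][0] for n in self.names])
        hi = np.array([self.bounds[n][1] for n in self.names])
        return lo, hi


@dataclass
class FitResult:
    parameters: dict[str, float]
    cell: CellParameters
    cost: float
    convergence: list[float]  # best cost per generation, non-increasing
    seed: int
    n_evaluations: int
    elapsed_s: float = 0.0


def apply_parameters(base: CellParameters, names: list[str],
                     values: np.ndarray) -> CellParameters:
    """Return a copy of ``base`` with the named fit parameters set."""
    params = base
    channels = dict(params.channels)
    cond = dict(params.conductances)
    for name, val in zip(names, values):
        kind, channel, which = name.split(":")
        if kind == "g":
            gs, ga = cond.get(channel, (0.0, 0.0))
            cond[channel] = (float(val), ga) if which == "soma" else (gs, float(val))
        elif kind == "vhalf":
            fieldn = "v_half_act" if which == "act" else "v_half_inact"
            channels[channel] = replace(channels[channel], **{fieldn: float(val)})
        else:
            raise ValueError(f"unknown parameter kind in {name!r}")
    return replace(params, conductances=cond, channels=channels)


def _extract(target: FeatureTarget, trace) -> float | None:
    name = target.feature
    if name == "ap_count":
        return float(len(feat.detect_spikes(trace)))
    if name in ("resting_v", "steady_v"):
        return float(trace.v_soma[-1]) if name == "steady_v" else float(trace.v_soma[0])
    if name == "first_spike_latency":
        return feat.first_spike_latency(trace, target.stim_onset)
    if name == "latency_after_burst":
        return feat.first_spike_latency(trace, target.stim_onset,
                                        skip_initial_burst=True)
    if name == "ap_amplitude":
        spikes = feat.detect_spikes(trace)
        if len(spikes) == 0:
            return None
        return feat.ap_amplitude(trace, spikes[0])
    if name == "isi_diff":
        return feat.isi_adaptation(feat.detect_spikes(trace))
    raise AssertionError(name)


#: settling time used when scoring candidates (ms); candidates start from
#: gate steady state so a short settle suffices
COST_SETTLE_MS = 1000.0


def _cost_batch(cells: list[CellParameters],
                targets: list[FeatureTarget]) -> np.ndarray:
    """Cost of each candidate cell; one batched simulation per protocol."""
    costs = np.zeros(len(cells))
    by_proto: dict[StimulusProtocol, list[FeatureTarget]] = {}
    for t in targets:
        by_proto.setdefault(t.protocol, []).append(t)
    for proto, tlist in by_proto.items():
        try:
            traces = simulate_current_clamp_batch(cells, proto,
                                                  settle_ms=COST_SETTLE_MS)
        except IntegrationError:
            # rerun individually so one divergent candidate does not
            # penalise the whole population
            traces = []
            for c in cells:
                try:
                    traces.append(simulate_current_clamp_batch(
                        [c], proto, settle_ms=COST_SETTLE_MS)[0])
                except IntegrationError:
                    traces.append(None)
        for b, trace in enumerate(traces):
            if trace is None:
                costs[b] = PENALTY
                continue
            for t in tlist:
                value = _extract(t, trace)
                if value is None:
                    costs[b] += PENALTY * t.weight
                else:
                    costs[b] += t.weight * ((value - t.target) / t.tolerance) ** 2
    return costs


def feature_cost(candidate: CellParameters,
                 targets: list[FeatureTarget]) -> float:
    """Weighted squared feature mismatch of one candidate (>= 0)."""
    return float(_cost_batch([candidate], targets)[0])


def reference_recovery_targets(base: CellParameters,
                               step_pa: float = 47.0) -> list[FeatureTarget]:
    """Noise-free feature targets computed from a reference cell.

    The standard recovery task: match the AP count and post-burst
    first-spike latency of an 800-ms step plus the resting potential, all
    simulated from ``base`` itself, so the generating parameters are the
    known optimum.
    """
    proto = StimulusProtocol(
        "current_clamp", [(100.0, 0.0), (800.0, step_pa), (100.0, 0.0)]
    )
    trace = simulate_current_clamp_batch([base], proto,
                                         settle_ms=COST_SETTLE_MS)[0]
    count = float(len(feat.detect_spikes(trace)))
    latency = feat.first_spike_latency(trace, 100.0, skip_initial_burst=True)
    targets = [
        FeatureTarget("ap_count", proto, count, weight=1.0, tolerance=0.5),
        FeatureTarget("resting_v", proto, float(trace.v_soma[0]),
                      weight=1.0, tolerance=0.5),
    ]
    if latency is not None:
        targets.append(FeatureTarget("latency_after_burst", proto, latency,
                                     weight=1.0, tolerance=5.0,
                                     stim_onset=100.0))
    return targets


def fit_de(
    bounds: ParameterBounds,
    targets: list[FeatureTarget],
    base: CellParameters,
    seed: int = 0,
    population: int = 40,
    generations: int = 100,
    mutation: float = 0.8,
    recombination: float = 0.9,
    tol: float = 0.0,
    cost_fn=None,
) -> FitResult:
    """Differential-evolution fit of the bounded parameters.

    ``cost_fn(values_matrix) -> costs`` may replace the feature cost (used by
    self-tests); by default candidates are scored with :func:`feature_cost`
    on a vectorised population.  The best-cost record is non-increasing and
    the whole run is reproducible from ``seed``.
    """
    if population < 4:
        raise ValueError("differential evolution needs a population >= 4")
    names = bounds.names
    lo, hi = bounds.as_arrays()
    n_eval = 0

    if cost_fn is None:
        def cost_fn(x: np.ndarray) -> np.ndarray:  # x: (n_params, S)
            cells = [apply_parameters(base, names, x[:, s])
                     for s in range(x.shape[1])]
            return _cost_batch(cells, targets)

    def objective(x: np.ndarray) -> np.ndarray:
        nonlocal n_eval
        x = np.atleast_2d(x.T).T  # (n_params, S)
        if x.ndim == 1:
            x = x[:, None]
        n_eval += x.shape[1]
        return cost_fn(x)

    record: list[float] = []

    def callback(xk, convergence=None):
        record.append(float(objective(xk[:, None] if xk.ndim == 1 else xk)[0]))

    if np.all(lo == hi):
        # degenerate zero-volume bounds: evaluate the single point
        x = lo.copy()
        cost = float(objective(x[:, None])[0])
        return FitResult(dict(zip(names, x)), apply_parameters(base, names, x),
                         cost, [cost], seed, 1)

    t0 = time.perf_counter()
    res = differential_evolution(
        objective,
        list(zip(lo, hi)),
        strategy="rand1bin",
        mutation=mutation,
        recombination=recombination,
        popsize=max(population // len(names), 4),
        maxiter=generations,
        seed=seed,
        tol=tol,
        polish=False,
        vectorized=True,
        updating="deferred",
        callback=callback,
        init="sobol",
    )
    best = np.asarray(res.x, dtype=float)
    # enforce a non-increasing best-so-far record
    running = []
    cur = np.inf
    for c in record:
        cur = min(cur, c)
        running.append(cur)
    cost = float(res.fun)
    running.append(min(cur, cost))
    return FitResult(
        parameters=dict(zip(names, best)),
        cell=apply_parameters(base, names, best),
        cost=cost,
        convergence=running,
        seed=seed,
        n_evaluations=n_eval,
        elapsed_s=time.perf_counter() - t0,
    )
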