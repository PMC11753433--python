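"""In-silico counterparts of the study's model conditions.

Four manipulations of the calibrated reference cell, all static changes of
maximal conductances:

* ``control`` — the calibrated reference (gKv1 = 41.7 nS soma / 23 nS axon);
* ``deprived`` — monocular-deprivation analogue: gKv1 raised to
  101.7 / 83 nS;
* ``dtx`` — dendrotoxin analogue: gKv1 = 0 in both compartments;
* ``ltpie`` — intrinsic-potentiation analogue: gKv1 halved;
* ``tta_p2`` — T-type blocker analogue: gT = 0.

No plasticity kinetics are modelled: the biochemical cascade linking spiking
to Kv1 down-regulation is represented only by the static conductance change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import features as feat
from .cell import (CellParameters, StimulusProtocol, simulate_current_clamp_batch,
                   simulate_voltage_clamp)

__all__ = [
    "ConditionSpec",
    "CONDITIONS",
    "apply_condition",
    "compare_conditions",
    "induction_protocol",
    "dtx_sensitive_current",
]

DEPRIVED_GKV1 = (101.7, 83.0)  # nS (soma, axon)


@dataclass(frozen=True)
class ConditionSpec:
    name: str
    gkv1_absolute: tuple[float, float] | None = None  # nS (soma, axon)
    gkv1_factor: float | None = None
    t_current_enabled: bool = True


CONDITIONS: dict[str, ConditionSpec] = {
    "control": ConditionSpec("control"),
    "deprived": ConditionSpec("deprived", gkv1_absolute=DEPRIVED_GKV1),
    "dtx": ConditionSpec("dtx", gkv1_absolute=(0.0, 0.0)),
    "ltpie": ConditionSpec("ltpie", gkv1_factor=0.5),
    "tta_p2": ConditionSpec("tta_p2", t_current_enabled=False),
}


def apply_condition(base: CellParameters, cond: ConditionSpec | str) -> CellParameters:
    """Parameters of one condition derived from the calibrated reference."""
    if isinstance(cond, str):
        try:
            cond = CONDITIONS[cond]
        except KeyError:
            raise ValueError(f"unknown condition {cond!r}") from None
    params = base
    if cond.gkv1_absolute is not None:
        params = params.with_conductance("Kv1", *cond.gkv1_absolute)
    elif cond.gkv1_factor is not None:
        params = params.scaled("Kv1", cond.gkv1_factor)
    if not cond.t_current_enabled:
        params = params.with_conductance("T", 0.0, 0.0)
    return params


def _condition_features(params: CellParameters, currents: np.ndarray,
                        step_ms: float, holding_bias: float) -> pd.DataFrame:
    proto = StimulusProtocol(
        "current_clamp", [(100.0, 0.0), (step_ms, 1.0), (100.0, 0.0)],
        holding_bias=holding_bias,
    )
    traces = simulate_current_clamp_batch(
        [params] * len(currents), proto, scale=np.asarray(currents, dtype=float)
    )
    rows = []
    for amp, tr in zip(currents, traces):
        spikes = feat.detect_spikes(tr)
        rows.append({
            "current_pA": float(amp),
            "ap_count": len(spikes),
            "first_spike_latency_ms": feat.first_spike_latency(tr, 100.0),
            "latency_after_burst_ms": feat.first_spike_latency(
                tr, 100.0, skip_initial_burst=True),
            "isi_diff_ms": feat.isi_adaptation(spikes),
        })
    return pd.DataFrame(rows)


def compare_conditions(
    base: CellParameters,
    cond_a: ConditionSpec | str,
    cond_b: ConditionSpec | str,
    currents,
    step_ms: float = 800.0,
    holding_bias: float = 0.0,
) -> pd.DataFrame:
    """Per-current feature table for two conditions plus deltas (b - a).

    The f-I scan runs from the reference holding regime (default 0 pA bias,
    i.e. the cell's -76 mV resting state).
    """
    currents = np.asarray(list(currents), dtype=float)
    if currents.size == 0:
        raise ValueError("current range is empty")
    name_a = cond_a if isinstance(cond_a, str) else cond_a.name
    name_b = cond_b if isinstance(cond_b, str) else cond_b.name
    if name_a == name_b:
        name_a, name_b = f"{name_a}_a", f"{name_b}_b"
    fa = _condition_features(apply_condition(base, cond_a), currents,
                             step_ms, holding_bias)
    fb = _condition_features(apply_condition(base, cond_b), currents,
                             step_ms, holding_bias)
    out = fa.merge(fb, on="current_pA", suffixes=(f"_{name_a}", f"_{name_b}"))
    out["d_ap_count"] = out[f"ap_count_{name_b}"] - out[f"ap_count_{name_a}"]
    la, lb = out[f"latency_after_burst_ms_{name_a}"], out[f"latency_after_burst_ms_{name_b}"]
    out["d_latency_after_burst_ms"] = lb - la
    return out


def induction_protocol(
    train_freq: float = 40.0,
    pulses_per_train: int = 15,
    train_interval: float = 10.0,
    duration: float = 10.0,
    pulse_width_ms: float = 2.0,
    pulse_pa: float = 1500.0,
    holding_bias: float = 0.0,
    dt: float = 0.025,
) -> StimulusProtocol:
    """Current-pulse analogue of the 40-Hz induction stimulation.

    Trains of ``pulses_per_train`` brief suprathreshold pulses at
    ``train_freq`` (Hz), one train every ``train_interval`` seconds, for
    ``duration`` minutes: the canonical 15-pulse 40-Hz train at 0.1 Hz for
    10 min delivers 900 pulses.  Frequency sets the spacing inside a train,
    not the pulse count.
    """
    if min(train_freq, pulses_per_train, train_interval, duration) <= 0:
        raise ValueError("all protocol arguments must be positive")
    if not 2.0 <= pulse_width_ms <= 5.0:
        raise ValueError("pulse width outside the 2-5 ms protocol range")
    period_ms = 1000.0 / train_freq
    gap_ms = period_ms - pulse_width_ms
    if gap_ms <= 0:
        raise ValueError("pulse width exceeds the inter-pulse period")
    n_trains = int(round(duration * 60.0 / train_interval))
    segments: list[tuple[float, float]] = []
    train_ms = pulses_per_train * period_ms
    rest_ms = train_interval * 1000.0 - train_ms
    if rest_ms <= 0:
        raise ValueError("train longer than the train interval")
    for _ in range(n_trains):
        for _ in range(pulses_per_train):
            segments.append((pulse_width_ms, pulse_pa))
            segments.append((gap_ms, 0.0))
        segments.append((rest_ms, 0.0))
    return StimulusProtocol("current_clamp", segments,
                            holding_bias=holding_bias, dt=dt)


def count_protocol_pulses(protocol: StimulusProtocol) -> int:
    """Number of nonzero pulses in a pulse-train protocol."""
    return sum(1 for _, level in protocol.segments if level != 0.0)


def dtx_sensitive_current(
    params: CellParameters,
    v_from: float,
    v_to: float,
    settle_at_step_ms: float = 2000.0,
    block_t_current: bool = True,
) -> float:
    """Steady DTx-sensitive (Kv1-mediated) clamp current at ``v_to`` (pA).

    In-silico analogue of the dendrotoxin subtraction protocol: the cell is
    clamped (whole-cell space clamp) from ``v_from`` to ``v_to`` with Kv1
    intact and with gKv1 = 0 everywhere, and the steady clamp currents are
    subtracted.
    The T-type current is blocked by default, as in the recordings the
    protocol emulates.
    """
    if v_from >= v_to:
        raise ValueError("v_from must be below v_to")
    if block_t_current:
        params = apply_condition(params, "tta_p2")
    blocked = apply_condition(params, "dtx")
    proto = StimulusProtocol(
        "voltage_clamp", [(200.0, v_from), (settle_at_step_ms, v_to)]
    )
    i_on = simulate_voltage_clamp(params, proto).i_clamp[-1]
    i_off = simulate_voltage_clamp(blocked, proto).i_clamp[-1]
    return float(i_on - i_off)
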