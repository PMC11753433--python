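"""Surrogate "recordings": model traces plus calibrated Gaussian noise.

These stand in for experimental current-clamp sweeps so that feature
extraction and parameter recovery can be validated against known ground
truth.  The noise model is additive iid Gaussian on the sampled voltage
(default SD 0.2 mV); electrode artefacts, bridge-balance error and
series-resistance filtering are deliberately not emulated.

Seeding: the master seed and the sweep index form the entropy of one
``numpy.random.default_rng([seed, sweep_index])`` stream per sweep, so any
sweep is reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from .cell import CellParameters, StimulusProtocol, Trace, simulate_current_clamp
from .io import write_trace

__all__ = ["SurrogateSpec", "generate_surrogate", "fixture_suite"]

DEFAULT_NOISE_SD = 0.2  # mV


@dataclass(frozen=True)
class SurrogateSpec:
    params: CellParameters
    protocol: StimulusProtocol
    noise_sd: float = DEFAULT_NOISE_SD  # mV
    n_sweeps: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if self.n_sweeps < 1:
            raise ValueError("need at least one sweep")


def generate_surrogate(spec: SurrogateSpec) -> tuple[list[Trace], dict]:
    """Noisy sweeps plus a ground-truth manifest.

    With ``noise_sd = 0`` every sweep is bit-identical to the clean
    simulation.  The manifest records the true parameters, protocol and
    per-sweep seeds.
    """
    clean = simulate_current_clamp(spec.params, spec.protocol)
    sweeps = []
    for k in range(spec.n_sweeps):
        if spec.noise_sd == 0.0:
            v_s, v_a = clean.v_soma.copy(), clean.v_axon.copy()
        else:
            rng = np.random.default_rng([spec.seed, k])
            v_s = clean.v_soma + rng.normal(0.0, spec.noise_sd, len(clean))
            v_a = clean.v_axon + rng.normal(0.0, spec.noise_sd, len(clean))
        meta = dict(clean.metadata)
        meta.update(sweep=k, master_seed=spec.seed, noise_sd_mV=spec.noise_sd)
        sweeps.append(Trace(t=clean.t.copy(), v_soma=v_s, v_axon=v_a, metadata=meta))
    manifest = {
        "seed": spec.seed,
        "n_sweeps": spec.n_sweeps,
        "noise_sd_mV": spec.noise_sd,
        "conductances_nS": {k: list(v) for k, v in spec.params.conductances.items()},
        "e_leak_mV": spec.params.e_leak,
        "protocol": {
            "mode": spec.protocol.mode,
            "segments": [list(s) for s in spec.protocol.segments],
            "holding_bias_pA": spec.protocol.holding_bias,
            "dt_ms": spec.protocol.dt,
        },
    }
    return sweeps, manifest


def fixture_suite(out_dir, base: CellParameters, seed: int = 0,
                  noise_sd: float = DEFAULT_NOISE_SD,
                  record_stride: int = 8) -> pd.DataFrame:
    """Write the canonical surrogate test set and return its manifest table.

    Per condition (control / deprived / dtx / ltpie): 800-ms steps at
    45-59 pA (2-pA grid) from the 0-pA holding regime, one -20 pA / 250 ms
    input-resistance pulse, and one voltage-clamp family (-80 to -50 mV).
    Clean feature values of each sweep are recorded in the manifest so
    round-trip extraction can be checked against them.
    """
    from .cell import simulate_voltage_clamp
    from .experiments import apply_condition

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    sweep_idx = 0
    conditions = ("control", "deprived", "dtx", "ltpie")
    currents = [45.0, 47.0, 49.0, 51.0, 53.0, 55.0, 57.0, 59.0]
    for cond in conditions:
        params = apply_condition(base, cond)
        for amp in currents:
            proto = StimulusProtocol(
                "current_clamp",
                [(100.0, 0.0), (800.0, amp), (100.0, 0.0)],
            )
            spec = SurrogateSpec(params, proto, noise_sd=noise_sd,
                                 n_sweeps=1, seed=seed + sweep_idx)
            (sweep,), _ = generate_surrogate(spec)
            clean = simulate_current_clamp(params, proto)
            spikes = feat.detect_spikes(clean)
            name = f"{cond}_step_{amp:.0f}pA.tsv"
            _decimate(sweep, record_stride)
            write_trace(out / name, sweep)
            rows.append({
                "file": name, "condition": cond, "kind": "step",
                "current_pA": amp, "noise_sd_mV": noise_sd,
                "ap_count": len(spikes),
                "latency_after_burst_ms": feat.first_spike_latency(
                    clean, 100.0, skip_initial_burst=True),
            })
            sweep_idx += 1
        rin_proto = StimulusProtocol(
            "current_clamp", [(100.0, 0.0), (250.0, -20.0), (150.0, 0.0)]
        )
        spec = SurrogateSpec(params, rin_proto, noise_sd=noise_sd,
                             n_sweeps=1, seed=seed + sweep_idx)
        (sweep,), _ = generate_surrogate(spec)
        clean = simulate_current_clamp(params, rin_proto)
        name = f"{cond}_rin.tsv"
        _decimate(sweep, record_stride)
        write_trace(out / name, sweep)
        rows.append({
            "file": name, "condition": cond, "kind": "rin",
            "current_pA": -20.0, "noise_sd_mV": noise_sd,
            "ap_count": 0,
            "latency_after_burst_ms": None,
        })
        sweep_idx += 1
        vc = StimulusProtocol("voltage_clamp", [(200.0, -80.0), (500.0, -50.0)])
        tr = simulate_voltage_clamp(params, vc)
        _decimate(tr, record_stride)
        name = f"{cond}_vclamp.tsv"
        write_trace(out / name, tr)
        rows.append({
            "file": name, "condition": cond, "kind": "vclamp",
            "current_pA": None, "noise_sd_mV": 0.0, "ap_count": None,
            "latency_after_burst_ms": None,
        })
        sweep_idx += 1
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def _decimate(trace: Trace, stride: int) -> None:
    if stride <= 1:
        return
    trace.t = trace.t[::stride]
    trace.v_soma = trace.v_soma[::stride]
    trace.v_axon = trace.v_axon[::stride]
    if trace.i_clamp is not None:
        trace.i_clamp = trace.i_clamp[::stride]
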