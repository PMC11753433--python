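"""Delimited-text trace I/O and YAML parameter files.

Traces are tab-separated columns (t_ms, v_soma_mV, v_axon_mV[, i_clamp_pA])
with a sidecar ``<name>.json`` metadata block.  Voltages written at full
float precision round-trip exactly.  An optional liquid-junction-potential
correction can be applied when importing external recordings (recorded
potentials are often reported uncorrected; the model's voltages are true
membrane potentials).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .cell import CellParameters, StimulusProtocol, Trace
from .channels import ChannelSpec, TauSpec

__all__ = [
    "write_trace",
    "read_trace",
    "save_cell",
    "load_cell",
    "save_protocol",
    "load_protocol",
]


def write_trace(path, trace: Trace) -> None:
    path = Path(path)
    cols = [trace.t, trace.v_soma, trace.v_axon]
    header = "t_ms\tv_soma_mV\tv_axon_mV"
    if trace.i_clamp is not None:
        cols.append(trace.i_clamp)
        header += "\ti_clamp_pA"
    np.savetxt(path, np.column_stack(cols), delimiter="\t", header=header,
               comments="", fmt="%.17g")
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(trace.metadata, indent=1, sort_keys=True, default=str)
    )


def read_trace(path, junction_correction_mv: float = 0.0) -> Trace:
    """Read a delimited trace; optionally subtract a junction potential
    (e.g. -13 mV for the recordings this package emulates)."""
    path = Path(path)
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    with open(path) as fh:
        names = fh.readline().strip().split("\t")
    meta_path = path.with_suffix(path.suffix + ".json")
    metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    cols = {name: data[:, i] for i, name in enumerate(names)}
    v_soma = cols["v_soma_mV"] + junction_correction_mv
    v_axon = cols.get("v_axon_mV")
    v_axon = v_axon + junction_correction_mv if v_axon is not None else np.full_like(v_soma, np.nan)
    return Trace(
        t=cols["t_ms"], v_soma=v_soma, v_axon=v_axon,
        i_clamp=cols.get("i_clamp_pA"), metadata=metadata,
    )


# ---------------------------------------------------------------------------
# parameter / protocol YAML


def _tau_dict(tau: TauSpec) -> dict:
    return {"tau_min": tau.tau_min, "tau_amp": tau.tau_amp, "v_mid": tau.v_mid,
            "slope_rise": tau.slope_rise, "slope_fall": tau.slope_fall}


def save_cell(path, params: CellParameters) -> None:
    payload = {
        "units": {"capacitance": "pF", "conductance": "nS",
                  "potential": "mV", "temperature": "degC"},
        "c_soma": params.c_soma,
        "c_axon": params.c_axon,
        "g_couple": params.g_couple,
        "e_leak": params.e_leak,
        "temperature": params.temperature,
        "conductances": {k: list(v) for k, v in params.conductances.items()},
        "channels": {
            name: {
                "activation_exponent": s.activation_exponent,
                "inactivation_exponent": s.inactivation_exponent,
                "v_half_act": s.v_half_act, "slope_act": s.slope_act,
                "v_half_inact": s.v_half_inact, "slope_inact": s.slope_inact,
                "tau_act": _tau_dict(s.tau_act),
                "tau_inact": _tau_dict(s.tau_inact),
                "e_rev": s.e_rev, "q10": s.q10, "t_ref": s.t_ref,
            }
            for name, s in params.channels.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_cell(path) -> CellParameters:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    channels = {}
    for name, c in d["channels"].items():
        c = dict(c)
        c["tau_act"] = TauSpec(**c["tau_act"])
        c["tau_inact"] = TauSpec(**c["tau_inact"])
        channels[name] = ChannelSpec(name=name, **c)
    return CellParameters(
        c_soma=d["c_soma"], c_axon=d["c_axon"], g_couple=d["g_couple"],
        e_leak=d["e_leak"], temperature=d.get("temperature", 30.0),
        conductances={k: tuple(v) for k, v in d["conductances"].items()},
        channels=channels,
    )


def save_protocol(path, protocol: StimulusProtocol) -> None:
    payload = {
        "mode": protocol.mode,
        "segments": [list(s) for s in protocol.segments],
        "holding_bias": protocol.holding_bias,
        "dt": protocol.dt,
        "n_repeats": protocol.n_repeats,
        "seed": protocol.seed,
        "units": {"duration": "ms", "current": "pA", "voltage": "mV"},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_protocol(path) -> StimulusProtocol:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d.pop("units", None)
    d["segments"] = [tuple(s) for s in d["segments"]]
    return StimulusProtocol(**d)
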