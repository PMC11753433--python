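"""Hodgkin-Huxley gating descriptions of the ionic currents of a dLGN relay cell.

Every current is written in the same canonical form

    I = g_max * m^p * h^q * (V - E_rev)        [pA; positive = outward]

with Boltzmann steady states

    x_inf(V) = 1 / (1 + exp(-(V - V_half) / k))

and a bell-shaped voltage-dependent time constant

    tau(V) = tau_min + tau_amp / (exp((V - v_mid)/s_rise) + exp(-(V - v_mid)/s_fall))

scaled by q10 ** ((t_ref - T) / 10) at simulation temperature T (degC).

Sign convention for the Boltzmann slope ``k``: activation gates have k > 0
(x_inf increases with depolarization), inactivation gates have k < 0.  The
hyperpolarization-activated HCN current is represented by an inactivation-type
gate, since its open probability falls with depolarization.

The channel inventory follows classic thalamocortical relay-cell models
(transient Na, delayed-rectifier K, A-type K, low-threshold T-type Ca, HCN,
leak) plus the low-threshold, slowly inactivating D-type Kv1 current that
delays the first spike and sets the rheobase of these cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Literal

import yaml

__all__ = [
    "TauSpec",
    "ChannelSpec",
    "steady_state",
    "time_constant",
    "channel_current",
    "default_channels",
    "dump_channels",
    "load_channels",
]

Gate = Literal["activation", "inactivation"]

CHANNEL_NAMES = ("Na", "Kdr", "A", "Kv1", "T", "H", "leak")


@dataclass(frozen=True)
class TauSpec:
    """Parameters of the bell-shaped time-constant curve (all ms / mV).

    ``tau_amp = 0`` degenerates to a voltage-independent constant ``tau_min``.
    """

    tau_min: float
    tau_amp: float = 0.0
    v_mid: float = 0.0
    slope_rise: float = 10.0
    slope_fall: float = 10.0

    def __post_init__(self) -> None:
        if self.tau_min <= 0:
            raise ValueError("tau_min must be strictly positive")
        if self.tau_amp < 0:
            raise ValueError("tau_amp must be >= 0")
        if self.slope_rise <= 0 or self.slope_fall <= 0:
            raise ValueError("tau slope parameters must be positive")

    def __call__(self, v: float) -> float:
        if self.tau_amp == 0.0:
            return self.tau_min
        return self.tau_min + self.tau_amp / (
            math.exp((v - self.v_mid) / self.slope_rise)
            + math.exp(-(v - self.v_mid) / self.slope_fall)
        )


@dataclass(frozen=True)
class ChannelSpec:
    """Kinetics and reversal potential of one ionic current.

    Units: potentials mV, time constants ms, temperatures degC.
    ``activation_exponent``/``inactivation_exponent`` are the HH gate powers
    p and q; a passive leak has p = q = 0.
    """

    name: str
    activation_exponent: int = 0
    inactivation_exponent: int = 0
    v_half_act: float = 0.0
    slope_act: float = 1.0
    v_half_inact: float = 0.0
    slope_inact: float = -1.0
    tau_act: TauSpec = field(default_factory=lambda: TauSpec(1.0))
    tau_inact: TauSpec = field(default_factory=lambda: TauSpec(1.0))
    e_rev: float = 0.0
    q10: float = 3.0
    t_ref: float = 30.0

    def __post_init__(self) -> None:
        if self.activation_exponent < 0 or self.inactivation_exponent < 0:
            raise ValueError("gate exponents must be >= 0")
        if self.q10 <= 0:
            raise ValueError("q10 must be positive")
        if self.activation_exponent > 0 and self.slope_act <= 0:
            raise ValueError("activation slope must be > 0 (increasing gate)")
        if self.inactivation_exponent > 0 and self.slope_inact >= 0:
            raise ValueError("inactivation slope must be < 0 (decreasing gate)")

    @property
    def is_gated(self) -> bool:
        return self.activation_exponent + self.inactivation_exponent > 0

    def has_gate(self, gate: Gate) -> bool:
        if gate == "activation":
            return self.activation_exponent > 0
        if gate == "inactivation":
            return self.inactivation_exponent > 0
        raise ValueError(f"unknown gate kind {gate!r}")


def _require_gate(spec: ChannelSpec, gate: Gate) -> None:
    if not spec.has_gate(gate):
        raise ValueError(f"channel {spec.name!r} has no {gate} gate")


def steady_state(spec: ChannelSpec, gate: Gate, v: float) -> float:
    """Boltzmann steady-state open fraction of one gate at voltage ``v`` (mV)."""
    _require_gate(spec, gate)
    if not math.isfinite(v):
        raise ValueError("voltage must be finite")
    if gate == "activation":
        vh, k = spec.v_half_act, spec.slope_act
    else:
        vh, k = spec.v_half_inact, spec.slope_inact
    return 1.0 / (1.0 + math.exp(-(v - vh) / k))


def time_constant(
    spec: ChannelSpec, gate: Gate, v: float, temperature: float | None = None
) -> float:
    """Gate relaxation time constant at ``v`` (ms), Q10-scaled to ``temperature``."""
    _require_gate(spec, gate)
    if not math.isfinite(v):
        raise ValueError("voltage must be finite")
    tau = spec.tau_act(v) if gate == "activation" else spec.tau_inact(v)
    if temperature is None:
        return tau
    return tau * spec.q10 ** ((spec.t_ref - temperature) / 10.0)


def channel_current(
    spec: ChannelSpec,
    gate_states: dict[str, float],
    v: float,
    g_max: float,
) -> float:
    """Instantaneous ohmic current in pA (positive = outward).

    ``gate_states`` maps "activation"/"inactivation" to values in [0, 1];
    gates the current lacks may be omitted.
    """
    if g_max < 0:
        raise ValueError("g_max must be >= 0")
    open_frac = 1.0
    if spec.activation_exponent > 0:
        m = gate_states["activation"]
        if not 0.0 <= m <= 1.0:
            raise ValueError("activation gate state outside [0, 1]")
        open_frac *= m ** spec.activation_exponent
    if spec.inactivation_exponent > 0:
        h = gate_states["inactivation"]
        if not 0.0 <= h <= 1.0:
            raise ValueError("inactivation gate state outside [0, 1]")
        open_frac *= h ** spec.inactivation_exponent
    return g_max * open_frac * (v - spec.e_rev)


def default_channels(e_leak: float = -72.5) -> dict[str, ChannelSpec]:
    """The model's channel inventory with literature-style relay-cell kinetics.

    All time constants are stated at t_ref = 30 degC, the recording temperature
    the model targets, so the default simulation applies no Q10 rescaling.
    The leak reversal ``e_leak`` is a cell-level parameter threaded in here.
    """
    return {
        "Na": ChannelSpec(
            name="Na",
            activation_exponent=3,
            inactivation_exponent=1,
            v_half_act=-36.0,
            slope_act=6.5,
            v_half_inact=-55.0,
            slope_inact=-7.0,
            tau_act=TauSpec(0.04, 0.2, -40.0, 15.0, 15.0),
            tau_inact=TauSpec(0.5, 8.0, -60.0, 11.0, 11.0),
            e_rev=50.0,
        ),
        # slow deactivation below -50 mV gives the deep, long AHP that sets
        # the tonic firing rate of these cells
        "Kdr": ChannelSpec(
            name="Kdr",
            activation_exponent=4,
            v_half_act=-25.0,
            slope_act=8.0,
            tau_act=TauSpec(0.5, 20.0, -55.0, 12.0, 12.0),
            e_rev=-90.0,
        ),
        "A": ChannelSpec(
            name="A",
            activation_exponent=4,
            inactivation_exponent=1,
            v_half_act=-60.0,
            slope_act=8.5,
            v_half_inact=-78.0,
            slope_inact=-6.0,
            tau_act=TauSpec(0.5, 1.5, -60.0, 20.0, 20.0),
            tau_inact=TauSpec(8.0, 20.0, -75.0, 15.0, 15.0),
            e_rev=-90.0,
        ),
        # D-type current: low activation threshold, slow partial inactivation.
        "Kv1": ChannelSpec(
            name="Kv1",
            activation_exponent=1,
            inactivation_exponent=1,
            v_half_act=-41.0,
            slope_act=6.0,
            v_half_inact=-65.0,
            slope_inact=-12.0,
            tau_act=TauSpec(3.0, 12.0, -60.0, 15.0, 15.0),
            tau_inact=TauSpec(500.0),
            e_rev=-90.0,
        ),
        "T": ChannelSpec(
            name="T",
            activation_exponent=2,
            inactivation_exponent=1,
            v_half_act=-57.0,
            slope_act=6.2,
            v_half_inact=-81.0,
            slope_inact=-4.0,
            tau_act=TauSpec(0.6, 3.0, -75.0, 15.0, 15.0),
            tau_inact=TauSpec(20.0, 200.0, -88.0, 10.0, 10.0),
            # fixed Ca reversal; no intracellular Ca dynamics in this model
            e_rev=120.0,
        ),
        # hyperpolarization-activated: decreasing gate, hence inactivation-type
        "H": ChannelSpec(
            name="H",
            inactivation_exponent=1,
            v_half_inact=-75.0,
            slope_inact=-5.5,
            tau_inact=TauSpec(80.0, 150.0, -80.0, 15.0, 15.0),
            e_rev=-43.0,
        ),
        "leak": ChannelSpec(name="leak", e_rev=e_leak),
    }


# ---------------------------------------------------------------------------
# serialization


def _spec_to_dict(spec: ChannelSpec) -> dict:
    d = asdict(spec)
    d["units"] = {"potentials": "mV", "time_constants": "ms", "temperature": "degC"}
    return d


def dump_channels(channels: dict[str, ChannelSpec], path) -> None:
    """Write the channel inventory as a human-readable YAML file."""
    payload = {name: _spec_to_dict(spec) for name, spec in channels.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_channels(path) -> dict[str, ChannelSpec]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    out = {}
    for name, d in payload.items():
        d.pop("units", None)
        d["tau_act"] = TauSpec(**d["tau_act"])
        d["tau_inact"] = TauSpec(**d["tau_inact"])
        out[name] = ChannelSpec(**d)
    return out
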