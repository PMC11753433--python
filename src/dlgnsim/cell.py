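"""Two-compartment relay-cell membrane model and clamp-protocol execution.

The cell is a somato-dendritic compartment coupled to an axonal (AIS)
compartment by a fixed ohmic conductance.  Compartments are isopotential;
surface area is absorbed into the capacitances (pF) and absolute maximal
conductances (nS).  Current localization: the A-type and T-type currents and
HCN live in the somato-dendritic compartment only; Na, Kdr and Kv1 are
present in both compartments; leak is present in both.

Voltages are true membrane potentials (any liquid-junction correction is the
concern of imported recordings, not of the model).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from . import _engine
from .channels import ChannelSpec, default_channels

__all__ = [
    "CellParameters",
    "StimulusProtocol",
    "Trace",
    "IntegrationError",
    "simulate_current_clamp",
    "simulate_voltage_clamp",
    "find_holding_current",
    "steady_state_voltage",
]

SOMA, AXON = 0, 1

#: channels restricted to the somato-dendritic compartment
_SOMA_ONLY = ("A", "T", "H")


class IntegrationError(RuntimeError):
    """Raised when the integrator state leaves the guard band."""

    def __init__(self, step: int, dt: float):
        self.step = step
        self.time_ms = step * dt
        super().__init__(
            f"integration failure at step {step} (t = {self.time_ms:.3f} ms)"
        )


class ProtocolError(RuntimeError):
    """Raised when a protocol target cannot be realized (e.g. spiking holding)."""


@dataclass(frozen=True)
class CellParameters:
    """Geometry, coupling and per-compartment maximal conductances.

    ``conductances`` maps channel name -> (g_soma, g_axon) in nS.  Channels
    absent from the mapping have zero conductance everywhere.
    """

    c_soma: float  # pF
    c_axon: float  # pF
    g_couple: float  # nS
    e_leak: float  # mV
    conductances: dict[str, tuple[float, float]]
    temperature: float = 30.0  # degC
    channels: dict[str, ChannelSpec] | None = None

    def __post_init__(self) -> None:
        if self.c_soma <= 0 or self.c_axon <= 0:
            raise ValueError("capacitances must be positive")
        if self.g_couple <= 0:
            raise ValueError("coupling conductance must be positive")
        for name, (gs, ga) in self.conductances.items():
            if gs < 0 or ga < 0:
                raise ValueError(f"negative conductance for {name}")
            if name in _SOMA_ONLY and ga != 0:
                raise ValueError(f"{name} current is somato-dendritic only")
        if self.channels is None:
            object.__setattr__(self, "channels", default_channels(self.e_leak))

    def with_conductance(self, name: str, g_soma: float, g_axon: float) -> "CellParameters":
        cond = dict(self.conductances)
        cond[name] = (g_soma, g_axon)
        return replace(self, conductances=cond)

    def scaled(self, name: str, factor: float) -> "CellParameters":
        gs, ga = self.conductances.get(name, (0.0, 0.0))
        return self.with_conductance(name, gs * factor, ga * factor)


@dataclass(frozen=True)
class StimulusProtocol:
    """Piecewise-constant clamp command.

    ``segments`` is an ordered list of (duration_ms, level); levels are pA in
    current clamp (added on top of ``holding_bias``) and mV in voltage clamp.
    """

    mode: Literal["current_clamp", "voltage_clamp"]
    segments: tuple[tuple[float, float], ...]
    holding_bias: float = 0.0  # pA
    dt: float = 0.025  # ms
    n_repeats: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(
            (float(d), float(level)) for d, level in self.segments
        ))
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        for d, _ in self.segments:
            if d <= 0 or not math.isfinite(d):
                raise ValueError("segment durations must be positive and finite")

    @property
    def total_duration(self) -> float:
        return sum(d for d, _ in self.segments)

    def command(self) -> np.ndarray:
        """Per-step command values, length total_duration/dt."""
        chunks = [
            np.full(int(round(d / self.dt)), level, dtype=np.float64)
            for d, level in self.segments
        ]
        return np.concatenate(chunks)


@dataclass
class Trace:
    """Uniformly sampled simulation output."""

    t: np.ndarray  # ms
    v_soma: np.ndarray  # mV
    v_axon: np.ndarray  # mV
    i_clamp: np.ndarray | None = None  # pA (voltage clamp only)
    metadata: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def __len__(self) -> int:
        return len(self.t)


# ---------------------------------------------------------------------------
# packing


_KIN_COLS = 17


def _pack_kinetics(params: CellParameters) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build (kin, comp, g) arrays for one parameter set (batch dim added later)."""
    qfac = {}
    instances = []
    for name, (gs, ga) in params.conductances.items():
        spec = params.channels[name]
        qfac[name] = spec.q10 ** ((spec.t_ref - params.temperature) / 10.0)
        instances.append((name, SOMA, gs))
        if name not in _SOMA_ONLY:
            instances.append((name, AXON, ga))
    ni = len(instances)
    kin = np.zeros((ni, _KIN_COLS))
    comp = np.zeros(ni, dtype=np.int64)
    g = np.zeros(ni)
    for i, (name, c, gval) in enumerate(instances):
        spec = params.channels[name]
        f = qfac[name]
        kin[i] = [
            spec.activation_exponent, spec.inactivation_exponent,
            spec.v_half_act, spec.slope_act, spec.v_half_inact, spec.slope_inact,
            spec.tau_act.tau_min * f, spec.tau_act.tau_amp * f,
            spec.tau_act.v_mid, spec.tau_act.slope_rise, spec.tau_act.slope_fall,
            spec.tau_inact.tau_min * f, spec.tau_inact.tau_amp * f,
            spec.tau_inact.v_mid, spec.tau_inact.slope_rise, spec.tau_inact.slope_fall,
            spec.e_rev if name != "leak" else params.e_leak,
        ]
        comp[i] = c
        g[i] = gval
    return kin, comp, g


def parameter_hash(params: CellParameters) -> str:
    kin, comp, g = _pack_kinetics(params)
    hsh = hashlib.sha1()
    for arr in (kin, comp.astype(np.float64), g):
        hsh.update(np.ascontiguousarray(arr).tobytes())
    hsh.update(np.array([params.c_soma, params.c_axon, params.g_couple,
                         params.temperature]).tobytes())
    return hsh.hexdigest()


class _Packed:
    """Batched engine-ready arrays; batch members may differ in g and kinetics."""

    def __init__(self, params_list: list[CellParameters]):
        packs = [_pack_kinetics(p) for p in params_list]
        comp0 = packs[0][1]
        for _, comp, _ in packs[1:]:
            if not np.array_equal(comp, comp0):
                raise ValueError("batch members must share channel inventory")
        self.kin = np.stack([k for k, _, _ in packs])
        self.comp = comp0
        self.g = np.stack([g for _, _, g in packs])
        self.cs = np.array([p.c_soma for p in params_list])
        self.ca = np.array([p.c_axon for p in params_list])
        self.gc = np.array([p.g_couple for p in params_list])

    @property
    def batch(self) -> int:
        return self.kin.shape[0]

    def init_state(self, v0: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        B, NI = self.g.shape
        v = np.full((B, 2), float(v0))
        m = np.ones((B, NI))
        h = np.ones((B, NI))
        _engine.init_gates(self.kin, self.comp, v, m, h)
        return v, m, h


def _run(packed: _Packed, v, m, h, stim, scale, bias, dt, stride, mode):
    S = len(stim)
    if S % stride:
        raise ValueError("stride must divide the number of steps")
    R = S // stride + 1
    B = packed.batch
    vout = np.empty((R, B, 2))
    iout = np.zeros((R, B))
    bad = _engine.run(packed.kin, packed.comp, packed.g, packed.cs, packed.ca,
                      packed.gc, v, m, h, stim, scale, bias, dt, stride, mode,
                      vout, iout)
    if bad >= 0:
        raise IntegrationError(bad, dt)
    return vout, iout


_DEFAULT_SETTLE_MS = 2000.0
_settle_cache: dict[tuple, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _settled_state(packed: _Packed, params_key: str, bias: np.ndarray, dt: float,
                   settle_ms: float, mode: int = _engine.MODE_CC,
                   v_cmd: float | None = None):
    """State after settling at a constant holding bias (or clamp command)."""
    key = (params_key, bias.tobytes(), dt, settle_ms, mode, v_cmd)
    if key in _settle_cache:
        v, m, h = _settle_cache[key]
        return v.copy(), m.copy(), h.copy()
    v0 = -76.0 if v_cmd is None else v_cmd
    v, m, h = packed.init_state(v0)
    S = int(round(settle_ms / dt))
    stim = np.zeros(S) if mode == _engine.MODE_CC else np.full(S, float(v_cmd))
    _run(packed, v, m, h, stim, np.ones(packed.batch), bias, dt, S, mode)
    _settle_cache[key] = (v.copy(), m.copy(), h.copy())
    if len(_settle_cache) > 256:
        _settle_cache.pop(next(iter(_settle_cache)))
    return v, m, h


def _batch_key(params_list: list[CellParameters]) -> str:
    return "|".join(parameter_hash(p) for p in params_list)


def simulate_current_clamp_batch(
    params_list: list[CellParameters],
    protocol: StimulusProtocol,
    scale: np.ndarray | None = None,
    settle_ms: float = _DEFAULT_SETTLE_MS,
    record_stride: int = 1,
) -> list[Trace]:
    """Simulate one current-clamp protocol over a batch of parameter sets.

    ``scale`` multiplies the time-varying part of the command per batch member
    (the holding bias is applied unscaled), which turns an f-I scan into a
    single kernel call.
    """
    if protocol.mode != "current_clamp":
        raise ValueError("protocol is not current clamp")
    packed = _Packed(params_list)
    B = packed.batch
    scale = np.ones(B) if scale is None else np.asarray(scale, dtype=np.float64)
    bias = np.full(B, float(protocol.holding_bias))
    dt = protocol.dt
    v, m, h = _settled_state(packed, _batch_key(params_list), bias, dt, settle_ms)
    stim = protocol.command()
    vout, _ = _run(packed, v, m, h, stim, scale, bias, dt, record_stride,
                   _engine.MODE_CC)
    t = np.arange(vout.shape[0]) * dt * record_stride
    meta = {
        "mode": "current_clamp",
        "segments": [list(s) for s in protocol.segments],
        "holding_bias_pA": protocol.holding_bias,
        "dt_ms": dt,
        "settle_ms": settle_ms,
    }
    return [
        Trace(t=t, v_soma=vout[:, b, 0].copy(), v_axon=vout[:, b, 1].copy(),
              metadata={**meta, "scale": float(scale[b]),
                        "parameter_hash": parameter_hash(params_list[b])})
        for b in range(B)
    ]


def simulate_current_clamp(
    params: CellParameters,
    protocol: StimulusProtocol,
    settle_ms: float = _DEFAULT_SETTLE_MS,
    record_stride: int = 1,
) -> Trace:
    """Current-clamp simulation after settling at the holding bias.

    Deterministic: identical (params, protocol, dt) give bit-identical traces.
    """
    return simulate_current_clamp_batch([params], protocol,
                                        settle_ms=settle_ms,
                                        record_stride=record_stride)[0]


def simulate_voltage_clamp(
    params: CellParameters,
    protocol: StimulusProtocol,
    settle_ms: float = _DEFAULT_SETTLE_MS,
    record_stride: int = 1,
    space_clamp: bool = True,
) -> Trace:
    """Voltage clamp of the cell.

    By default both compartments follow the command (whole-cell space
    clamp: the AIS of these small cells is electrotonically compact), and
    the clamp current balances the capacitive jump plus all ionic currents.
    With ``space_clamp=False`` only the somatic compartment is clamped, the
    axon integrates freely, and the coupling current enters the balance —
    axonal escape spikes are then possible, as in poorly clamped cells.
    """
    if protocol.mode != "voltage_clamp":
        raise ValueError("protocol is not voltage clamp")
    packed = _Packed([params])
    dt = protocol.dt
    stim = protocol.command()
    mode = _engine.MODE_VC_FULL if space_clamp else _engine.MODE_VC
    v, m, h = _settled_state(packed, parameter_hash(params), np.zeros(1), dt,
                             settle_ms, mode=mode, v_cmd=stim[0])
    vout, iout = _run(packed, v, m, h, stim, np.ones(1), np.zeros(1), dt,
                      record_stride, mode)
    t = np.arange(vout.shape[0]) * dt * record_stride
    return Trace(
        t=t, v_soma=vout[:, 0, 0], v_axon=vout[:, 0, 1], i_clamp=iout[:, 0],
        metadata={
            "mode": "voltage_clamp",
            "space_clamp": space_clamp,
            "segments": [list(s) for s in protocol.segments],
            "dt_ms": dt,
            "parameter_hash": parameter_hash(params),
        },
    )


def steady_state_voltage(
    params: CellParameters,
    bias_pa: float = 0.0,
    settle_ms: float = 3000.0,
    dt: float = 0.025,
) -> float:
    """Settled somatic potential under a constant bias current (mV)."""
    packed = _Packed([params])
    v, m, h = _settled_state(packed, parameter_hash(params),
                             np.array([float(bias_pa)]), dt, settle_ms)
    return float(v[0, 0])


def _is_quiescent(params: CellParameters, bias: float, dt: float = 0.025) -> bool:
    proto = StimulusProtocol("current_clamp", [(500.0, 0.0)], holding_bias=bias, dt=dt)
    tr = simulate_current_clamp(params, proto, settle_ms=1500.0, record_stride=8)
    return float(np.ptp(tr.v_soma)) < 5.0


def find_holding_current(
    params: CellParameters,
    target_v: float,
    tol_mv: float = 0.1,
    max_bias_pa: float = 200.0,
    step_pa: float = 10.0,
    settle_ms: float = 3000.0,
) -> float:
    """Bias current (pA) whose settled somatic voltage equals ``target_v``.

    Walks outward from 0 pA in ``step_pa`` increments until the settled
    voltage brackets the target, then bisects.  Raises ``ProtocolError`` if
    the cell starts spiking spontaneously before the target is reached (no
    quiescent fixed point at that potential) or if ``max_bias_pa`` is
    exceeded.
    """
    from scipy.optimize import brentq

    if not -100.0 < target_v < -40.0:
        raise ValueError("target potential outside supported range (-100, -40) mV")

    def f(bias: float) -> float:
        return steady_state_voltage(params, bias, settle_ms=settle_ms) - target_v

    f0 = f(0.0)
    if abs(f0) < tol_mv / 4:
        return 0.0
    direction = 1.0 if f0 < 0 else -1.0
    prev = 0.0
    bias = direction * step_pa
    while abs(bias) <= max_bias_pa:
        if not _is_quiescent(params, bias):
            raise ProtocolError(
                f"cell spikes spontaneously at bias {bias:.1f} pA before "
                f"reaching {target_v} mV; holding target unreachable"
            )
        if f(bias) * f0 <= 0:
            return float(brentq(f, min(prev, bias), max(prev, bias),
                                xtol=tol_mv / 2.0))
        prev = bias
        bias += direction * step_pa
    raise ProtocolError(
        f"target {target_v} mV not reached within +/-{max_bias_pa} pA"
    )


def trace_to_json_metadata(trace: Trace) -> str:
    return json.dumps(trace.metadata, indent=1, sort_keys=True)
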