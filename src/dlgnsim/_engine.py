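"""Fixed-step integration core (numba).

State layout, batched over B parameter sets so that current scans and
population-based fitting share one compiled kernel:

* ``kin``  (B, NI, 17) — per channel-instance kinetics:
  [p, q, vh_act, k_act, vh_inact, k_inact,
   ta_min, ta_amp, ta_vm, ta_s1, ta_s2,
   ti_min, ti_amp, ti_vm, ti_s1, ti_s2, e_rev]
  (tau entries already Q10-scaled to the simulation temperature)
* ``comp`` (NI,) int64 — 0 soma, 1 axon
* ``g``    (B, NI) nS, ``cs``/``ca`` (B,) pF, ``gc`` (B,) nS coupling
* ``v``    (B, 2) mV, ``m``/``h`` (B, NI) gate states in [0, 1]

Scheme: exponential Euler on gates (evaluated at the pre-step voltage),
forward Euler on voltages.  Exponential Euler keeps gates inside [0, 1]
by construction whenever x_inf does.  Units: pA = nS * mV; dV/dt in mV/ms
= pA / pF.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

MODE_CC = 0
MODE_VC = 1       # somatic compartment clamped, axon free
MODE_VC_FULL = 2  # both compartments clamped (whole-cell space clamp)

#: hard integration guard (mV); excursions beyond this abort the run
V_GUARD = 500.0


@njit(cache=True, fastmath=False)
def _tau_of_v(v, tmin, tamp, vm, s1, s2):
    if tamp == 0.0:
        return tmin
    return tmin + tamp / (math.exp((v - vm) / s1) + math.exp(-(v - vm) / s2))


@njit(cache=True, fastmath=False)
def _xinf(v, vh, k):
    return 1.0 / (1.0 + math.exp(-(v - vh) / k))


@njit(cache=True, fastmath=False)
def init_gates(kin, comp, v, m, h):
    """Set every gate to its steady state at the current voltages."""
    B, NI = m.shape
    for b in range(B):
        for i in range(NI):
            vloc = v[b, comp[i]]
            if kin[b, i, 0] > 0.0:
                m[b, i] = _xinf(vloc, kin[b, i, 2], kin[b, i, 3])
            else:
                m[b, i] = 1.0
            if kin[b, i, 1] > 0.0:
                h[b, i] = _xinf(vloc, kin[b, i, 4], kin[b, i, 5])
            else:
                h[b, i] = 1.0


@njit(cache=True, fastmath=False)
def _ionic(kin, comp, g, b, i, vs, va, m, h):
    """Instantaneous current of instance i in batch b (pA, outward > 0)."""
    vloc = vs if comp[i] == 0 else va
    open_frac = 1.0
    p = kin[b, i, 0]
    q = kin[b, i, 1]
    if p > 0.0:
        open_frac *= m[b, i] ** p
    if q > 0.0:
        open_frac *= h[b, i] ** q
    return g[b, i] * open_frac * (vloc - kin[b, i, 16])


@njit(cache=True, fastmath=False)
def run(kin, comp, g, cs, ca, gc, v, m, h,
        stim, scale, bias, dt, stride, mode, vout, iout):
    """Integrate S = len(stim) steps, recording every ``stride`` steps.

    ``stim`` is the time-varying command (pA in current clamp, mV in voltage
    clamp); the injected somatic current in current clamp is
    ``bias[b] + scale[b] * stim[step]``.  Returns the index of the first step
    at which the state left the guard band, or -1 on success.
    """
    B, NI = g.shape
    S = stim.shape[0]
    r = 0
    for step in range(S + 1):
        if step % stride == 0:
            for b in range(B):
                vout[r, b, 0] = v[b, 0]
                vout[r, b, 1] = v[b, 1]
                if mode != MODE_CC:
                    # clamp current from the current state; the capacitive
                    # term is the discrete jump the command applies this step
                    dcmd = (stim[step] - v[b, 0]) / dt if step < S else 0.0
                    ion_s = 0.0
                    ion_a = 0.0
                    for i in range(NI):
                        cur = _ionic(kin, comp, g, b, i, v[b, 0], v[b, 1], m, h)
                        if comp[i] == 0:
                            ion_s += cur
                        else:
                            ion_a += cur
                    if mode == MODE_VC:
                        iout[r, b] = cs[b] * dcmd + ion_s + gc[b] * (v[b, 0] - v[b, 1])
                    else:
                        iout[r, b] = (cs[b] + ca[b]) * dcmd + ion_s + ion_a
            r += 1
        if step == S:
            break

        for b in range(B):
            if mode != MODE_CC:
                v[b, 0] = stim[step]
                if mode == MODE_VC_FULL:
                    v[b, 1] = stim[step]
            vs = v[b, 0]
            va = v[b, 1]

            # gate update (exponential Euler at pre-step voltage)
            for i in range(NI):
                vloc = vs if comp[i] == 0 else va
                if kin[b, i, 0] > 0.0:
                    minf = _xinf(vloc, kin[b, i, 2], kin[b, i, 3])
                    taum = _tau_of_v(vloc, kin[b, i, 6], kin[b, i, 7],
                                     kin[b, i, 8], kin[b, i, 9], kin[b, i, 10])
                    m[b, i] += (minf - m[b, i]) * (1.0 - math.exp(-dt / taum))
                if kin[b, i, 1] > 0.0:
                    hinf = _xinf(vloc, kin[b, i, 4], kin[b, i, 5])
                    tauh = _tau_of_v(vloc, kin[b, i, 11], kin[b, i, 12],
                                     kin[b, i, 13], kin[b, i, 14], kin[b, i, 15])
                    h[b, i] += (hinf - h[b, i]) * (1.0 - math.exp(-dt / tauh))

            # membrane currents with updated gates, pre-step voltages
            ion_s = 0.0
            ion_a = 0.0
            for i in range(NI):
                cur = _ionic(kin, comp, g, b, i, vs, va, m, h)
                if comp[i] == 0:
                    ion_s += cur
                else:
                    ion_a += cur
            i_couple = gc[b] * (vs - va)

            if mode == MODE_CC:
                i_inj = bias[b] + scale[b] * stim[step]
                v[b, 0] = vs + dt / cs[b] * (i_inj - ion_s - i_couple)
            if mode != MODE_VC_FULL:
                v[b, 1] = va + dt / ca[b] * (i_couple - ion_a)

            if not (-V_GUARD < v[b, 0] < V_GUARD) or not (-V_GUARD < v[b, 1] < V_GUARD):
                return step
            if v[b, 0] != v[b, 0] or v[b, 1] != v[b, 1]:
                return step
    return -1
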