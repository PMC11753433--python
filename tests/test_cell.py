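"""Integrator and clamp-protocol tests: RC closed form, convergence,
charge balance, holding-current inversion."""

import numpy as np
import pytest

from dlgnsim.cell import (CellParameters, StimulusProtocol, Trace,
                          find_holding_current, simulate_current_clamp,
                          simulate_voltage_clamp, steady_state_voltage)


def rc_response(t, di_pa, g_ns, c_pf, v0):
    """Closed-form step response of an isopotential RC compartment."""
    tau = c_pf / g_ns
    return v0 + (di_pa / g_ns) * (1.0 - np.exp(-t / tau))


class TestPassiveOracle:
    def test_matches_rc_closed_form(self, passive_cell, step_protocol):
        # soma+axon behave as one RC with g = 2 nS, c = 66 pF (tight coupling)
        proto = step_protocol(-20.0, dur_ms=400.0)
        tr = simulate_current_clamp(passive_cell, proto)
        on = np.searchsorted(tr.t, 100.0)
        t_rel = tr.t[on:] - tr.t[on]
        mask = t_rel <= 5 * (66.0 / 2.0)
        expected = rc_response(t_rel[mask], -20.0, 2.0, 66.0, -76.0)
        err = np.abs(tr.v_soma[on:][mask][1:] - expected[1:])
        assert err.max() < 0.01 * 10.0  # <1% of the 10-mV amplitude

    def test_amplitude_is_di_over_g(self, passive_cell, step_protocol):
        tr = simulate_current_clamp(passive_cell, step_protocol(-20.0))
        v_end = tr.v_soma[np.searchsorted(tr.t, 899.0)]
        assert v_end == pytest.approx(-86.0, abs=0.02)

    def test_passive_holding_current_analytic(self, passive_cell):
        # target rest + 5 mV needs 5 mV * 2 nS = 10 pA
        bias = find_holding_current(passive_cell, -71.0)
        assert bias == pytest.approx(10.0, abs=0.2)


class TestIntegration:
    def test_step_halving_convergence(self, reference, step_protocol):
        v = {}
        for dt in (0.025, 0.0125):
            tr = simulate_current_clamp(reference, step_protocol(-20.0, dt=dt))
            v[dt] = tr.v_soma[:: 1 if dt == 0.025 else 2]
        dv = np.abs(v[0.025] - v[0.0125])
        assert dv.max() < 0.5

    def test_determinism(self, reference, step_protocol):
        a = simulate_current_clamp(reference, step_protocol(47.0))
        b = simulate_current_clamp(reference, step_protocol(47.0))
        assert np.array_equal(a.v_soma, b.v_soma)
        assert np.array_equal(a.v_axon, b.v_axon)

    def test_trace_shape_and_finiteness(self, reference, step_protocol):
        proto = step_protocol(47.0)
        tr = simulate_current_clamp(reference, proto)
        assert len(tr) == int(round(proto.total_duration / proto.dt)) + 1
        assert np.all(np.isfinite(tr.v_soma)) and np.all(np.isfinite(tr.v_axon))
        assert np.allclose(np.diff(tr.t), proto.dt)

    def test_voltage_bounds(self, reference, step_protocol):
        for amp in (-20.0, 47.0, 180.0):
            tr = simulate_current_clamp(reference, step_protocol(amp))
            assert tr.v_soma.min() > -120 and tr.v_soma.max() < 60

    def test_gates_bounded_along_trajectory(self, reference, step_protocol):
        # spot-check by re-deriving gate trajectories is heavy; instead assert
        # the integrator's structural guarantee via a spiking trace's sanity
        tr = simulate_current_clamp(reference, step_protocol(180.0))
        assert np.all(np.isfinite(tr.v_soma))


class TestChargeBalance:
    def test_steady_state_current_balance(self, reference):
        # at rest the net membrane current must vanish: inject nothing and
        # verify dV/dt ~ 0 at the end of a long settle
        proto = StimulusProtocol("current_clamp", [(3000.0, 0.0)])
        tr = simulate_current_clamp(reference, proto, settle_ms=3000.0)
        dvdt = np.diff(tr.v_soma[-100:]) / proto.dt  # mV/ms
        # |I_net| = C |dV/dt| < 0.1 pA
        assert np.abs(dvdt).max() * reference.c_soma < 0.1


class TestVoltageClamp:
    def test_leak_only_rest_gives_zero_current(self, passive_cell):
        proto = StimulusProtocol("voltage_clamp", [(500.0, -76.0)])
        tr = simulate_voltage_clamp(passive_cell, proto)
        assert abs(tr.i_clamp[-1]) < 1e-6

    def test_leak_only_step_is_ohmic(self, passive_cell):
        proto = StimulusProtocol("voltage_clamp", [(200.0, -76.0), (500.0, -66.0)])
        tr = simulate_voltage_clamp(passive_cell, proto)
        # soma leak 1.5 nS * 10 mV plus coupling toward the axon (0.5 nS leak)
        # with tight coupling the pair acts as 2 nS total -> 20 pA
        assert tr.i_clamp[-1] == pytest.approx(20.0, abs=0.05)

    def test_steady_current_equals_channel_sum(self, reference):
        from dlgnsim.channels import steady_state
        proto = StimulusProtocol("voltage_clamp", [(200.0, -80.0), (4000.0, -50.0)])
        tr = simulate_voltage_clamp(reference, proto)
        i_end = tr.i_clamp[-1]
        v = -50.0
        total = 0.0
        for name, (gs, ga) in reference.conductances.items():
            spec = reference.channels[name]
            frac = 1.0
            if spec.activation_exponent:
                frac *= steady_state(spec, "activation", v) ** spec.activation_exponent
            if spec.inactivation_exponent:
                frac *= steady_state(spec, "inactivation", v) ** spec.inactivation_exponent
            e = reference.e_leak if name == "leak" else spec.e_rev
            total += (gs + ga) * frac * (v - e)
        assert i_end == pytest.approx(total, rel=0.02, abs=1.0)


class TestHoldingCurrent:
    def test_rest_needs_no_current(self, reference):
        bias = find_holding_current(reference, steady_state_voltage(reference, 0.0))
        assert bias == pytest.approx(0.0, abs=0.5)

    def test_thirteen_pa_depolarizes_to_minus_69(self, reference):
        bias = find_holding_current(reference, -69.0)
        assert bias == pytest.approx(13.0, abs=1.5)

    def test_out_of_range_target_rejected(self, reference):
        with pytest.raises(ValueError):
            find_holding_current(reference, -30.0)


class TestProtocolValidation:
    def test_bad_segments_rejected(self):
        with pytest.raises(ValueError):
            StimulusProtocol("current_clamp", [])
        with pytest.raises(ValueError):
            StimulusProtocol("current_clamp", [(-5.0, 0.0)])
        with pytest.raises(ValueError):
            StimulusProtocol("current_clamp", [(100.0, 0.0)], dt=0.0)

    def test_cell_invariants(self):
        with pytest.raises(ValueError):
            CellParameters(c_soma=0.0, c_axon=6, g_couple=20, e_leak=-76,
                           conductances={"leak": (1.0, 1.0)})
        with pytest.raises(ValueError):
            CellParameters(c_soma=60, c_axon=6, g_couple=20, e_leak=-76,
                           conductances={"A": (10.0, 5.0), "leak": (1.0, 1.0)})
        with pytest.raises(ValueError):
            CellParameters(c_soma=60, c_axon=6, g_couple=20, e_leak=-76,
                           conductances={"leak": (-1.0, 1.0)})
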