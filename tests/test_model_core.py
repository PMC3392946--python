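"""Gating kinetics, ionic currents and the ODE right-hand side."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fsneuron import (BufferScheme, ModelParameters, NeuronState,
                      default_initial_state, default_rates, equilibrate,
                      find_equilibrium, integrate, ionic_currents, rhs,
                      sk_gate_kinetics, steady_state_gates, Stimulus,
                      detect_spikes)
from fsneuron.model import make_rhs


class TestSteadyStateGates:
    def test_hva_activation_midpoint(self):
        assert steady_state_gates(-6.0).a_inf == pytest.approx(0.5)

    def test_hva_activation_saturates(self):
        assert steady_state_gates(200.0).a_inf == pytest.approx(1.0, abs=1e-9)

    def test_hva_activation_hand_value(self):
        # 1/(1 + exp(-6/7.775)) at V = 0
        assert steady_state_gates(0.0).a_inf == pytest.approx(
            1.0 / (1.0 + math.exp(-6.0 / 7.775)), abs=1e-12)

    @given(V=st.floats(-100, 60))
    @settings(max_examples=60, deadline=None)
    def test_gates_bounded_and_taus_positive(self, V):
        g = steady_state_gates(V)
        for x in (g.m_inf, g.a_inf, g.h_inf, g.n1_inf, g.n3_inf):
            assert 0.0 < x < 1.0
        for tau in (g.tau_h, g.tau_n1, g.tau_n3):
            assert tau > 0.0

    def test_rate_positivity_on_grid(self, rates):
        rates.validate()  # raises if any alpha/beta <= 0 on [-100, 60]

    def test_linoid_singularity_resolved(self, rates):
        # beta_h is a linoid with V_half = -51.25; continuous through it
        b = rates.beta["h"]
        eps = 1e-9
        assert b(-51.25) == pytest.approx(b(-51.25 + eps), rel=1e-5)
        assert np.isfinite(b(-51.25))

    def test_nonfinite_voltage_rejected(self):
        with pytest.raises(ValueError):
            steady_state_gates(float("nan"))


class TestSKGate:
    def test_half_activation_at_K_SK(self):
        k_inf, _ = sk_gate_kinetics(0.5)
        assert k_inf == pytest.approx(0.5)

    def test_mass_action_relaxation_time(self):
        p = ModelParameters(k_on_sk=0.4, k_off_sk=0.2)
        _, tau = sk_gate_kinetics(0.5, p)
        assert tau == pytest.approx(1.0 / (0.4 * 0.5 + 0.2))  # 2.5 ms

    def test_activation_at_resting_calcium(self):
        k_inf, _ = sk_gate_kinetics(0.07)
        assert k_inf == pytest.approx(0.07 / 0.57, rel=1e-6)

    def test_literal_tau_variant(self):
        p = ModelParameters(literal_tau_k=True)
        _, tau = sk_gate_kinetics(0.5, p)
        assert tau == pytest.approx(1.0)  # 1/(K_SK + Ca) read as ms

    def test_nonpositive_calcium_rejected(self):
        with pytest.raises(ValueError):
            sk_gate_kinetics(0.0)


class TestIonicCurrents:
    @staticmethod
    def _state(V, **kw):
        base = dict(V=V, h=0.5, n1=0.2, n3=0.3, k=0.4, Ca_i=0.1)
        base.update(kw)
        return NeuronState(**base)

    def test_leak_vanishes_at_reversal(self):
        c = ionic_currents(self._state(-68.0))
        assert c.I_leak == pytest.approx(0.0, abs=1e-12)

    def test_sk_vanishes_at_potassium_reversal(self):
        c = ionic_currents(self._state(-90.0, k=0.7))
        assert c.I_SK == pytest.approx(0.0, abs=1e-12)

    def test_sk_hand_value(self):
        # g_SK k^2 (V - V_K) = 2 * 1 * 20 pA
        c = ionic_currents(self._state(-70.0, k=1.0))
        assert c.I_SK == pytest.approx(40.0)

    def test_reversal_sign_structure(self):
        """Each current changes sign only at its reversal potential."""
        p = ModelParameters()
        for V in np.linspace(-100.0, 70.0, 69):
            c = ionic_currents(self._state(V), p)
            assert np.sign(c.I_Na) == np.sign(V - p.V_Na) or c.I_Na == 0
            for val in (c.I_Kv1, c.I_Kv3, c.I_SK):
                assert np.sign(val) == np.sign(V - p.V_K) or val == 0
            assert np.sign(c.I_Ca) == np.sign(V - p.V_Ca) or c.I_Ca == 0
            assert np.sign(c.I_leak) == np.sign(V - p.V_leak) or c.I_leak == 0


class TestRightHandSide:
    def test_pure_capacitor_slope(self):
        p = ModelParameters(g_Na=0, g_Kv1=0, g_Kv3=0, g_SK=0, g_Ca=0,
                            g_leak=0)
        y = default_initial_state(p, BufferScheme.none()).to_array(
            BufferScheme.none())
        dy = rhs(0.0, y, p, BufferScheme.none(), 30.0)
        assert dy[0] == pytest.approx(1.0)  # 30 pA / 30 pF = 1 mV/ms

    def test_vanishes_at_equilibrium(self, params):
        sch = BufferScheme.pv(1000.0)
        eq = find_equilibrium(params, sch, 20.0)
        dy = rhs(0.0, eq.y, params, sch, 20.0)
        assert np.max(np.abs(dy)) < 1e-8

    def test_resting_state_is_stationary(self, params, rest_state):
        """After burn-in at 0 pA the state is an equilibrium near the leak
        reversal (the model rests at -67.9 mV, just above V_leak; the
        biological reference value is about -70 mV)."""
        sch = BufferScheme.pv(1000.0)
        dy = rhs(0.0, rest_state.to_array(sch), params, sch, 0.0)
        assert abs(dy[0]) < 1e-6
        assert -72.0 < rest_state.V < -67.0

    def test_closure_matches_rhs(self, params):
        sch = BufferScheme.fast(100.0)
        y = default_initial_state(params, sch).to_array(sch)
        y[0] = -50.0
        f = make_rhs(params, sch, 25.0)
        assert np.array_equal(f(3.0, y),
                              rhs(3.0, y, params, sch, 25.0))


class TestTrajectoryInvariants:
    def test_gates_stay_in_unit_interval(self, pv1000_run):
        traj, _ = pv1000_run
        for arr in (traj.h, traj.n1, traj.n3, traj.k):
            assert arr.min() > -1e-6 and arr.max() < 1 + 1e-6

    def test_sk_knockout_decouples_voltage_from_buffer(self, params):
        """With g_SK = 0, calcium no longer feeds back on V: voltage traces
        are bit-identical across buffer concentrations."""
        p = params.with_overrides(g_SK=0.0)
        stim = Stimulus.hold(100.0, 1000.0)
        trajs = []
        for sch in (BufferScheme.none(), BufferScheme.pv(1000.0)):
            init = default_initial_state(p, sch)
            trajs.append(integrate(init, p, sch, stim))
        assert np.array_equal(trajs[0].V, trajs[1].V)
        s0 = detect_spikes(trajs[0]).times
        s1 = detect_spikes(trajs[1]).times
        assert np.array_equal(s0, s1) and len(s0) > 5


class TestNeuronState:
    def test_invariant_validation(self):
        with pytest.raises(ValueError):
            NeuronState(V=-70, h=1.5, n1=0, n3=0, k=0, Ca_i=0.1).validate()
        with pytest.raises(ValueError):
            NeuronState(V=-70, h=0, n1=0, n3=0, k=0, Ca_i=-1.0).validate()
        sch = BufferScheme.pv(10.0)
        with pytest.raises(ValueError):
            NeuronState(V=-70, h=0, n1=0, n3=0, k=0, Ca_i=0.1,
                        PVCa_i=8.0, PVMg_i=8.0).validate(sch)

    def test_array_roundtrip(self):
        sch = BufferScheme.pv(100.0)
        s = NeuronState(V=-55.0, h=0.3, n1=0.1, n3=0.2, k=0.4, Ca_i=0.5,
                        PVCa_i=10.0, PVMg_i=80.0)
        back = NeuronState.from_array(s.to_array(sch), sch)
        assert back == s
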