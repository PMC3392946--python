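"""Calcium shell balance, buffer kinetics and occupancy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from fsneuron import (BufferScheme, ModelParameters, NeuronState,
                      buffering_capacity, calcium_derivatives,
                      default_initial_state, equilibrium_occupancy,
                      integrate, Stimulus)
from fsneuron.buffering import initial_bound_pools


def _state(Ca, scheme, params=None, **pools):
    p = params or ModelParameters()
    kw = dict(V=-70.0, h=0.5, n1=0.1, n3=0.1, k=0.2, Ca_i=Ca)
    kw.update(pools)
    return NeuronState(**kw)


class TestCalciumDerivatives:
    def test_influx_unit_conversion(self):
        """-1 pA of Ca current raises shell Ca by 1/(2 F A d) uM/ms."""
        p = ModelParameters(gamma=0.0)
        d = calcium_derivatives(_state(0.07, None), I_Ca=-1.0, params=p,
                                scheme=BufferScheme.none())
        assert d.dCa == pytest.approx(8.637e-3, rel=1e-3)

    def test_pure_clearance(self):
        d = calcium_derivatives(_state(0.17, None),
                                I_Ca=0.0, scheme=BufferScheme.none())
        assert d.dCa == pytest.approx(-0.1)

    def test_equilibrium_is_stationary(self):
        p = ModelParameters()
        sch = BufferScheme.pv(500.0)
        b1, b2 = initial_bound_pools(p, sch)
        d = calcium_derivatives(
            _state(p.Ca_rest, sch, PVCa_i=b1, PVMg_i=b2), I_Ca=0.0,
            params=p, scheme=sch)
        assert abs(d.dCa) < 1e-9
        assert abs(d.dPVCa) < 1e-9 and abs(d.dPVMg) < 1e-9

    def test_mg_binding_does_not_consume_calcium(self):
        """dCa subtracts the Ca-bound flux only; Mg binding acts through
        site occupancy."""
        p = ModelParameters(gamma=0.0)
        sch = BufferScheme.pv(100.0)
        s = _state(0.2, sch, PVCa_i=10.0, PVMg_i=50.0)
        d = calcium_derivatives(s, I_Ca=0.0, params=p, scheme=sch)
        free = sch.B_T - s.PVCa_i - s.PVMg_i
        expect_dpvca = sch.k_on_ca * 0.2 * free - sch.k_off_ca * 10.0
        assert d.dPVCa == pytest.approx(expect_dpvca)
        assert d.dCa == pytest.approx(-expect_dpvca)

    def test_corrupt_state_rejected(self):
        sch = BufferScheme.fast(10.0)
        with pytest.raises(ValueError):
            calcium_derivatives(_state(0.1, sch, BCa_i=20.0), I_Ca=0.0,
                                scheme=sch)


class TestEquilibriumOccupancy:
    def test_fast_buffer_half_saturation(self):
        occ = equilibrium_occupancy(0.01, scheme=BufferScheme.fast(100.0))
        assert occ.bound_ca == pytest.approx(0.5)

    def test_slow_buffer_saturation(self):
        occ = equilibrium_occupancy(1e4, scheme=BufferScheme.slow(100.0))
        assert occ.bound_ca == pytest.approx(1.0, abs=1e-3)

    @given(Ca=st.floats(1e-3, 10.0), Mg=st.floats(0.0, 1000.0))
    @settings(max_examples=40, deadline=None)
    def test_fractions_sum_to_one(self, Ca, Mg):
        occ = equilibrium_occupancy(Ca, Mg, BufferScheme.pv(100.0))
        assert occ.free + occ.bound_ca + occ.bound_mg == pytest.approx(1.0)
        assert min(occ.free, occ.bound_ca, occ.bound_mg) >= 0.0

    def test_pv_closed_form_matches_ode_relaxation(self):
        """Competitive-equilibrium closed form vs brute-force relaxation of
        the binding ODEs at clamped (Ca, Mg)."""
        sch = BufferScheme.pv(1.0)  # fractions directly
        rng = np.random.default_rng(42)
        for _ in range(20):
            Ca = float(10 ** rng.uniform(-2, 1))
            Mg = float(rng.uniform(0.0, 1000.0))

            def f(_, y):
                pvca, pvmg = y
                free = 1.0 - pvca - pvmg
                return [sch.k_on_ca * Ca * free - sch.k_off_ca * pvca,
                        sch.k_on_mg * Mg * free - sch.k_off_mg * pvmg]

            sol = solve_ivp(f, (0.0, 5e5), [0.0, 0.0], rtol=1e-12,
                            atol=1e-14, method="LSODA")
            pvca, pvmg = sol.y[:, -1]
            occ = equilibrium_occupancy(Ca, Mg, sch)
            assert occ.bound_ca == pytest.approx(pvca, abs=1e-6)
            assert occ.bound_mg == pytest.approx(pvmg, abs=1e-6)

    def test_nonpositive_calcium_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_occupancy(0.0, scheme=BufferScheme.fast(1.0))


class TestBufferingCapacity:
    def test_no_buffer(self):
        assert buffering_capacity(0.1, BufferScheme.none()) == 0.0

    def test_hand_value(self):
        # B_T K_D/(Ca+K_D)^2 = 1000*0.01/0.02^2
        assert buffering_capacity(0.01, BufferScheme.fast(1000.0)) == \
            pytest.approx(25000.0)

    def test_monotone_decreasing_in_calcium(self):
        sch = BufferScheme.slow(500.0)
        caps = [buffering_capacity(ca, sch)
                for ca in np.logspace(-3, 1, 30)]
        assert all(a > b for a, b in zip(caps, caps[1:]))


class TestTrajectoryLevel:
    def test_mass_conservation_along_train(self, pv1000_run):
        """Free PV (B_T - PVCa - PVMg) stays within [0, B_T] at every
        sample of a 5 s spike train: the bound pools never leak mass."""
        traj, _ = pv1000_run
        B_T = traj.scheme.B_T
        bound = traj.b1 + traj.b2
        assert bound.max() <= B_T * (1 + 1e-6)
        assert traj.b1.min() >= -1e-6 * B_T
        assert traj.b2.min() >= -1e-6 * B_T

    def test_mg_is_not_a_state_variable(self, params):
        from dataclasses import fields
        names = {f.name for f in fields(NeuronState)}
        assert "Mg_i" not in names and "Mg" not in names

    def test_no_buffer_equals_zero_concentration(self, params):
        """kind='none' and a PV scheme at B_T = 0 produce identical
        calcium trajectories."""
        stim = Stimulus.hold(100.0, 500.0)
        out = []
        for sch in (BufferScheme.none(), BufferScheme.pv(0.0)):
            init = default_initial_state(params, sch)
            out.append(integrate(init, params, sch, stim))
        assert np.array_equal(out[0].Ca, out[1].Ca)
        assert np.array_equal(out[0].V, out[1].V)

    def test_kernel_calcium_matches_buffering_module(self, params):
        """The compiled RHS and the reference implementation agree on the
        calcium/buffer derivatives."""
        from fsneuron import rhs, ionic_currents
        sch = BufferScheme.pv(200.0)
        s = NeuronState(V=-50.0, h=0.4, n1=0.1, n3=0.3, k=0.3, Ca_i=0.8,
                        PVCa_i=30.0, PVMg_i=120.0)
        cur = ionic_currents(s, params)
        ref = calcium_derivatives(s, cur.I_Ca, params, sch)
        dy = rhs(0.0, s.to_array(sch), params, sch, 0.0)
        assert dy[6] == pytest.approx(ref.dCa, rel=1e-12)
        assert dy[7] == pytest.approx(ref.dPVCa, rel=1e-12)
        assert dy[8] == pytest.approx(ref.dPVMg, rel=1e-12)
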