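"""Stimulus protocols, the RK4 integrator and equilibration."""

import math
import warnings

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from fsneuron import (BufferScheme, ModelParameters, Stimulus,
                      build_protocol, default_initial_state, detect_spikes,
                      equilibrate, integrate)
from fsneuron.model import make_rhs
from fsneuron.simulate import Segment, rk4


class TestProtocols:
    def test_step_amplitude_and_bounds(self):
        stim = build_protocol("step", 100.0, 1000.0)
        assert stim(500.0) == pytest.approx(100.0)
        assert stim.window == (0.0, 1000.0)
        assert stim.total_duration == 1000.0

    def test_ramp_reaches_rate_times_duration(self):
        stim = build_protocol("ramp", duration=1000.0, ramp_rate=200.0)
        assert stim(1000.0) == pytest.approx(200.0)
        assert stim(500.0) == pytest.approx(100.0)

    def test_zero_step_is_identically_zero(self):
        stim = build_protocol("step", 0.0, 500.0)
        assert np.all(stim(np.linspace(0, 500, 31)) == 0.0)

    def test_pre_post_segments(self):
        stim = build_protocol("step", 50.0, 200.0, pre_ms=100.0,
                              post_ms=100.0)
        assert stim(50.0) == 0.0
        assert stim(150.0) == 50.0
        assert stim(350.0) == 0.0
        assert stim.window == (100.0, 300.0)

    def test_unknown_protocol_rejected(self):
        with pytest.raises(ValueError):
            build_protocol("chirp")

    def test_hold_segment_consistency(self):
        with pytest.raises(ValueError):
            Segment(10.0, "hold", 1.0, 2.0)
        with pytest.raises(ValueError):
            Segment(-1.0, "hold", 0.0, 0.0)


class TestRK4:
    def test_pure_capacitor_exact(self):
        """All conductances zero: V grows linearly, exact for RK4."""
        p = ModelParameters(g_Na=0, g_Kv1=0, g_Kv3=0, g_SK=0, g_Ca=0,
                            g_leak=0)
        sch = BufferScheme.none()
        init = default_initial_state(p, sch)
        traj = integrate(init, p, sch, Stimulus.hold(30.0, 100.0))
        assert traj.V[-1] == pytest.approx(init.V + 100.0, abs=1e-9)

    def test_scalar_exponential_decay(self):
        """dx/dt = -x integrated over 1 ms matches exp(-1) to 1e-10."""
        out = rk4(lambda t, y: -y, [1.0], 0.01, 100)
        assert out[-1, 0] == pytest.approx(math.exp(-1.0), abs=1e-10)

    def test_bitwise_determinism(self, params):
        sch = BufferScheme.pv(200.0)
        init = default_initial_state(params, sch)
        stim = Stimulus.hold(100.0, 300.0)
        a = integrate(init, params, sch, stim)
        b = integrate(init, params, sch, stim)
        assert np.array_equal(a.y, b.y)

    def test_matches_adaptive_reference(self, params, rest_state):
        """200 ms of the 100 pA step vs a tight-tolerance adaptive solve."""
        sch = BufferScheme.pv(1000.0)
        stim = Stimulus.hold(100.0, 200.0)
        traj = integrate(rest_state, params, sch, stim)
        f = make_rhs(params, sch, stim)
        ref = solve_ivp(f, (0.0, 200.0), rest_state.to_array(sch),
                        method="DOP853", rtol=1e-10, atol=1e-12,
                        t_eval=traj.t, max_step=1.0)
        assert ref.success
        assert np.max(np.abs(traj.V - ref.y[0])) < 0.5

    def test_dt_convergence_on_reference_run(self, params):
        """Halving dt leaves the spike count unchanged and shifts every
        spike time by < 0.1 ms (burn-in + 1 s, 100 pA, PV 1000 uM)."""
        sch = BufferScheme.pv(1000.0)
        stim = build_protocol("step", 100.0, 1000.0)
        spikes = {}
        for dt in (0.01, 0.005):
            state = equilibrate(params, sch, dt=dt)
            traj = integrate(state, params, sch, stim, dt=dt,
                             record_stride=max(1, round(0.05 / dt)))
            spikes[dt] = detect_spikes(traj).times
        assert len(spikes[0.01]) == len(spikes[0.005])
        assert np.max(np.abs(spikes[0.01] - spikes[0.005])) < 0.1

    def test_invalid_dt_rejected(self, params):
        sch = BufferScheme.none()
        init = default_initial_state(params, sch)
        with pytest.raises(ValueError):
            integrate(init, params, sch, Stimulus.hold(0.0, 10.0), dt=0.0)


class TestEquilibrate:
    def test_subthreshold_hold_settles(self, params):
        """20 pA is below the oscillation threshold: quiet steady state."""
        sch = BufferScheme.pv(1000.0)
        state, traj, residual = equilibrate(params, sch, hold_current=20.0,
                                            full_output=True)
        assert residual < 1e-3
        last = traj.V[traj.t >= traj.t[-1] - 1000.0]
        assert last.max() < 0.0  # no spikes
        assert state.V == pytest.approx(-57.6, abs=1.0)

    def test_suprathreshold_hold_keeps_spiking(self, params):
        """100 pA sustains periodic firing; equilibrate reports it."""
        sch = BufferScheme.pv(1000.0)
        with pytest.warns(RuntimeWarning, match="settle"):
            _, traj, _ = equilibrate(params, sch, hold_current=100.0,
                                     full_output=True)
        spikes = detect_spikes(traj)
        last = spikes.in_window((traj.t[-1] - 1000.0, traj.t[-1]))
        assert len(last) > 10

    def test_rest_calcium_near_resting_level(self, params, rest_state):
        assert rest_state.Ca_i >= params.Ca_rest
        assert rest_state.Ca_i == pytest.approx(params.Ca_rest, rel=0.1)


class TestTrajectoryIO:
    def test_csv_roundtrip(self, tmp_path, params):
        sch = BufferScheme.pv(100.0)
        init = default_initial_state(params, sch)
        traj = integrate(init, params, sch, Stimulus.hold(0.0, 10.0))
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        text = path.read_text()
        assert text.startswith("#") and params.hash() in text
        import pandas as pd
        df = pd.read_csv(path, comment="#")
        assert np.allclose(df.V_mV.to_numpy(), traj.V)
        for col in ("time_ms", "h", "n1", "n3", "k", "Ca_uM", "PVCa_uM",
                    "PVMg_uM", "I_SK_pA", "Iapp_pA"):
            assert col in df.columns
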