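"""Fixed-step RK4 integration, burn-in equilibration and current-clamp
stimulus protocols.

The production integrator is the classic fourth-order Runge-Kutta scheme with
a fixed step (default dt = 0.01 ms; halving dt shifts spike times of the
reference runs by well under 0.1 ms).  Runs are deterministic and bitwise
reproducible: the model has no stochastic elements.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernel
from ._kernel import NY, IV, IH, IN1, IN3, IK, ICA, IB1, IB2
from .buffering import initial_bound_pools
from .model import NeuronState, pack_params, rhs, steady_state_gates, \
    sk_gate_kinetics
from .parameters import ModelParameters, BufferScheme
from .rates import RateCoefficientSet, default_rates

__all__ = ["Segment", "Stimulus", "Trajectory", "build_protocol",
           "integrate", "equilibrate", "default_initial_state", "rk4"]

#: default integration step (ms) and recording stride (samples)
DT_DEFAULT = 0.01
STRIDE_DEFAULT = 5
BURN_IN_MS = 4000.0


@dataclass(frozen=True)
class Segment:
    duration: float          # ms
    mode: str                # "hold" | "ramp"
    start: float             # pA
    end: float               # pA

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("segment duration must be > 0")
        if self.mode not in ("hold", "ramp"):
            raise ValueError(f"unknown segment mode {self.mode!r}")
        if self.mode == "hold" and self.start != self.end:
            raise ValueError("hold segment must have start == end")


@dataclass(frozen=True)
class Stimulus:
    """Piecewise applied current I_app(t); 0 pA outside all segments.

    ``window`` marks the analysis window (typically the stimulus-on
    interval) in ms.
    """

    segments: tuple
    window: Optional[tuple] = None

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    def segments_array(self) -> np.ndarray:
        rows, t = [], 0.0
        for s in self.segments:
            rows.append([t, t + s.duration, s.start, s.end])
            t += s.duration
        return np.asarray(rows) if rows else np.zeros((0, 4))

    def __call__(self, t):
        seg = self.segments_array()
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.array([_kernel.stim_eval(seg, ti) for ti in t_arr])
        return out if np.ndim(t) else float(out[0])

    @classmethod
    def hold(cls, amplitude: float, duration: float) -> "Stimulus":
        return cls((Segment(duration, "hold", amplitude, amplitude),),
                   window=(0.0, duration))


def build_protocol(name: str, amplitude: float = 100.0,
                   duration: float = 1000.0, pre_ms: float = 0.0,
                   post_ms: float = 0.0, ramp_rate: float = 200.0,
                   segments: Optional[Sequence[Segment]] = None) -> Stimulus:
    """Standard current-clamp protocols.

    ``step``: 0 pA for ``pre_ms``, ``amplitude`` pA for ``duration``, 0 pA
    for ``post_ms``.  ``ramp``: linear 0 -> ramp_rate (pA/s) x duration.
    ``custom``: explicit ``segments``.
    """
    if min(pre_ms, post_ms) < 0 or duration <= 0:
        raise ValueError("durations must be non-negative (duration > 0)")
    segs: list[Segment] = []
    if pre_ms > 0:
        segs.append(Segment(pre_ms, "hold", 0.0, 0.0))
    if name == "step":
        segs.append(Segment(duration, "hold", amplitude, amplitude))
    elif name == "ramp":
        segs.append(Segment(duration, "ramp", 0.0, ramp_rate * duration / 1000.0))
    elif name == "custom":
        if not segments:
            raise ValueError("custom protocol requires segments")
        segs.extend(segments)
    else:
        raise ValueError(f"unknown protocol {name!r}")
    stim_end = pre_ms + (duration if name != "custom"
                         else sum(s.duration for s in segments))
    if post_ms > 0:
        segs.append(Segment(post_ms, "hold", 0.0, 0.0))
    return Stimulus(tuple(segs), window=(pre_ms, stim_end))


@dataclass
class Trajectory:
    """Uniformly sampled simulation output.

    ``y`` holds the raw kernel state vectors (one row per sample); named
    accessors and :meth:`to_frame` expose the physiological variables and
    the per-sample current breakdown.
    """

    t: np.ndarray
    y: np.ndarray
    params: ModelParameters
    scheme: BufferScheme
    stim: Stimulus
    dt: float
    stride: int
    rates: RateCoefficientSet = field(repr=False, default=None)

    def __post_init__(self):
        if self.rates is None:
            self.rates = default_rates()

    # ---- named views ---------------------------------------------------
    V = property(lambda self: self.y[:, IV])
    h = property(lambda self: self.y[:, IH])
    n1 = property(lambda self: self.y[:, IN1])
    n3 = property(lambda self: self.y[:, IN3])
    k = property(lambda self: self.y[:, IK])
    Ca = property(lambda self: self.y[:, ICA])
    b1 = property(lambda self: self.y[:, IB1])
    b2 = property(lambda self: self.y[:, IB2])

    @property
    def bound_fraction(self) -> np.ndarray:
        """Ca2+ occupancy of the buffer, [PVCa]/B_T or [BCa]/B_T."""
        if self.scheme.B_T == 0:
            return np.zeros_like(self.t)
        return self.b1 / self.scheme.B_T

    @property
    def I_app(self) -> np.ndarray:
        return self.stim(self.t)

    def state_at(self, i: int) -> NeuronState:
        return NeuronState.from_array(self.y[i], self.scheme,
                                      self.params.instantaneous_a)

    def final_state(self) -> NeuronState:
        return self.state_at(-1)

    def currents(self) -> dict:
        """Per-sample current breakdown (pA, positive outward)."""
        p = self.params
        R = self.rates.kernel_array()
        m_inf, a_inf = _kernel.gates_over(self.V, R)
        a = self.y[:, _kernel.IA] if not p.instantaneous_a else a_inf
        V = self.V
        return {
            "I_Na": p.g_Na * m_inf ** 3 * self.h * (V - p.V_Na),
            "I_Kv1": p.g_Kv1 * self.n1 ** 4 * (V - p.V_K),
            "I_Kv3": p.g_Kv3 * self.n3 ** 2 * (V - p.V_K),
            "I_SK": p.g_SK * self.k ** 2 * (V - p.V_K),
            "I_Ca": p.g_Ca * a ** 2 * (V - p.V_Ca),
            "I_leak": p.g_leak * (V - p.V_leak),
        }

    @property
    def I_SK(self) -> np.ndarray:
        p = self.params
        return p.g_SK * self.k ** 2 * (self.V - p.V_K)

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_ms": self.t, "V_mV": self.V, "h": self.h,
                "n1": self.n1, "n3": self.n3, "k": self.k, "Ca_uM": self.Ca}
        if self.scheme.kind == "pv":
            cols["PVCa_uM"] = self.b1
            cols["PVMg_uM"] = self.b2
        elif self.scheme.kind in ("slow", "fast"):
            cols["BCa_uM"] = self.b1
        for name, arr in self.currents().items():
            cols[name + "_pA"] = arr
        cols["Iapp_pA"] = self.I_app
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        header = (f"# fsneuron trajectory params={self.params.hash()} "
                  f"scheme={self.scheme.kind} B_T={self.scheme.B_T} "
                  f"dt={self.dt} stride={self.stride}\n")
        buf = io.StringIO()
        self.to_frame().to_csv(buf, index=False)
        with open(path, "w") as fh:
            fh.write(header)
            fh.write(buf.getvalue())


def _check_invariants(traj: Trajectory, tol: float = 1e-6) -> None:
    y, t = traj.y, traj.t
    gates = y[:, [IH, IN1, IN3, IK]]
    bad = np.where((gates < -tol) | (gates > 1 + tol))[0]
    if bad.size:
        raise RuntimeError(
            f"gating variable left [0,1] at t = {t[bad[0]]:.3f} ms")
    bad = np.where(y[:, ICA] <= 0)[0]
    if bad.size:
        raise RuntimeError(f"Ca went non-positive at t = {t[bad[0]]:.3f} ms")
    if traj.scheme.kind != "none":
        B_T = traj.scheme.B_T
        bound = (y[:, IB1] + y[:, IB2] if traj.scheme.kind == "pv"
                 else y[:, IB1])
        btol = tol * max(B_T, 1.0)
        bad = np.where((bound < -btol) | (bound > B_T + btol))[0]
        if bad.size:
            raise RuntimeError(
                f"buffer pools left [0, B_T] at t = {t[bad[0]]:.3f} ms")


def integrate(initial: NeuronState, params: ModelParameters,
              scheme: BufferScheme, stim: Stimulus,
              dt: float = DT_DEFAULT, record_stride: int = STRIDE_DEFAULT,
              duration: Optional[float] = None,
              rates: Optional[RateCoefficientSet] = None,
              check: bool = True) -> Trajectory:
    """Integrate the model with classic fixed-step RK4.

    The stimulus is evaluated at the RK4 substep times; samples are recorded
    every ``record_stride`` steps (including t = 0).  ``duration`` defaults
    to the stimulus duration.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rates = rates or default_rates()
    duration = stim.total_duration if duration is None else duration
    n_steps = int(round(duration / dt))
    P = pack_params(params)
    R = rates.kernel_array()
    code, BUF = scheme.kernel_arrays()
    y0 = initial.to_array(scheme)
    out, status = _kernel.rk4_run(y0, P, R, code, BUF,
                                  stim.segments_array(), dt, n_steps,
                                  record_stride)
    t = np.arange(out.shape[0]) * (dt * record_stride)
    if status >= 0:
        raise RuntimeError(
            f"integration diverged near t = {t[status]:.3f} ms; "
            "try a smaller dt")
    traj = Trajectory(t=t, y=out, params=params, scheme=scheme, stim=stim,
                      dt=dt, stride=record_stride, rates=rates)
    if check:
        _check_invariants(traj)
    return traj


def default_initial_state(params: ModelParameters,
                          scheme: BufferScheme,
                          V0: float = -70.0) -> NeuronState:
    """Canonical pre-burn-in state: gates at steady state for V0, calcium at
    rest, buffer pools at equilibrium with (Ca_rest, Mg_i)."""
    g = steady_state_gates(V0, None, params)
    k_inf, _ = sk_gate_kinetics(params.Ca_rest, params)
    b1, b2 = initial_bound_pools(params, scheme)
    kw = dict(V=V0, h=g.h_inf, n1=g.n1_inf, n3=g.n3_inf, k=k_inf,
              Ca_i=params.Ca_rest)
    if scheme.kind == "pv":
        kw.update(PVCa_i=b1, PVMg_i=b2)
    elif scheme.kind in ("slow", "fast"):
        kw.update(BCa_i=b1)
    if not params.instantaneous_a:
        kw["a"] = g.a_inf
    return NeuronState(**kw)


def equilibrate(params: ModelParameters, scheme: BufferScheme,
                hold_current: float = 0.0, duration: float = BURN_IN_MS,
                dt: float = DT_DEFAULT,
                rates: Optional[RateCoefficientSet] = None,
                residual_threshold: float = 1e-3,
                full_output: bool = False):
    """Burn-in: integrate ``duration`` ms at a holding current and return the
    final state.

    Starts from :func:`default_initial_state`.  If the residual derivative
    norm at the end exceeds ``residual_threshold`` (e.g. the cell fires
    spontaneously at the hold current) a warning is issued; with
    ``full_output`` the burn-in trajectory and residual norm are returned
    alongside the state.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    stim = Stimulus.hold(hold_current, duration)
    initial = default_initial_state(params, scheme)
    traj = integrate(initial, params, scheme, stim, dt=dt,
                     record_stride=max(1, int(round(1.0 / dt))), rates=rates)
    state = traj.final_state()
    dy = rhs(duration, state.to_array(scheme), params, scheme,
             hold_current, rates)
    residual = float(np.linalg.norm(dy))
    if residual > residual_threshold:
        warnings.warn(
            f"burn-in did not settle (|dy| = {residual:.3g}); the model may "
            f"be spontaneously active at {hold_current} pA", RuntimeWarning)
    if full_output:
        return state, traj, residual
    return state


def rk4(f: Callable, y0, dt: float, n_steps: int) -> np.ndarray:
    """Generic fixed-step RK4 on dy/dt = f(t, y) (reference/test helper).

    Returns the sampled solution at every step, shape (n_steps + 1,) + y0
    shape.  The production model integrator uses the compiled kernel; this
    helper exists for validating the scheme on systems with closed-form
    solutions.
    """
    y = np.atleast_1d(np.asarray(y0, dtype=float))
    out = np.empty((n_steps + 1,) + y.shape)
    out[0] = y
    for n in range(n_steps):
        t = n * dt
        k1 = np.asarray(f(t, y))
        k2 = np.asarray(f(t + dt / 2, y + dt / 2 * k1))
        k3 = np.asarray(f(t + dt / 2, y + dt / 2 * k2))
        k4 = np.asarray(f(t + dt, y + dt * k3))
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        out[n + 1] = y
    return out
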