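"""Equilibrium continuation, linear stability and oscillation-onset tooling.

Reconstructs the model's bifurcation structure in the applied current:
a branch of equilibria V_eq(I_app) with eigenvalues of the finite-difference
Jacobian, the Hopf point where the leading complex pair crosses the
imaginary axis, and the onset of persistent large-amplitude spiking located
by simulation bisection (the practical estimate of the saddle-node of limit
cycles; periodic-orbit continuation is deliberately out of scope).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from types import SimpleNamespace
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .model import NeuronState, active_indices, make_rhs
from .parameters import ModelParameters, BufferScheme
from .rates import RateCoefficientSet, default_rates
from .simulate import Stimulus, default_initial_state, equilibrate, integrate
from .analysis import detect_spikes

__all__ = ["EquilibriumPoint", "find_equilibrium", "continuation",
           "find_hopf", "bisect_onset", "find_oscillation_onset",
           "bifurcation_report"]


@dataclass
class EquilibriumPoint:
    """An equilibrium of the model at fixed I_app with its local stability."""

    I_app: float
    state: NeuronState
    y: np.ndarray                 # full kernel state vector
    eigenvalues: np.ndarray       # of the reduced (active-dim) Jacobian, ms^-1
    residual_norm: float

    @property
    def stable(self) -> bool:
        return bool(np.max(self.eigenvalues.real) < 0)

    @property
    def max_real_eig(self) -> float:
        return float(np.max(self.eigenvalues.real))

    @property
    def V(self) -> float:
        return float(self.y[0])


def _reduced_system(params, scheme, I_app, rates, y_template):
    idx = active_indices(params, scheme)
    full = make_rhs(params, scheme, float(I_app), rates)

    def f(x):
        y = y_template.copy()
        y[idx] = x
        return full(0.0, y)[idx]

    return idx, f


def _fd_jacobian(f: Callable, x: np.ndarray, rel: float = 1e-6,
                 floor: float = 1e-3) -> np.ndarray:
    """Central finite-difference Jacobian, relative step with absolute floor."""
    n = len(x)
    J = np.empty((n, n))
    for j in range(n):
        h = rel * max(abs(x[j]), floor)
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (np.asarray(f(xp)) - np.asarray(f(xm))) / (2 * h)
    return J


def _scalar_balance_state(params: ModelParameters, scheme: BufferScheme,
                          I_app: float, rates,
                          V_range=(-90.0, -20.0)) -> NeuronState:
    """Exact equilibrium candidate via the 1-D reduction in V.

    At any equilibrium the gates sit on their steady-state curves and shell
    calcium at its explicit fixed point (buffer fluxes vanish), so
    equilibria are exactly the roots of the scalar steady-state
    current-balance in V.
    """
    from scipy.optimize import brentq
    from .model import steady_state_gates, sk_gate_kinetics
    from .buffering import initial_bound_pools

    def balance(V):
        g = steady_state_gates(V, rates, params)
        I_Ca = params.g_Ca * g.a_inf ** 2 * (V - params.V_Ca)
        Ca_eq = params.Ca_rest + (-I_Ca * params.flux_conversion
                                  / max(params.gamma, 1e-12))
        k_inf, _ = sk_gate_kinetics(max(Ca_eq, 1e-12), params)
        I_sum = (params.g_Na * g.m_inf ** 3 * g.h_inf * (V - params.V_Na)
                 + params.g_Kv1 * g.n1_inf ** 4 * (V - params.V_K)
                 + params.g_Kv3 * g.n3_inf ** 2 * (V - params.V_K)
                 + params.g_SK * k_inf ** 2 * (V - params.V_K)
                 + I_Ca + params.g_leak * (V - params.V_leak))
        return -I_sum + I_app

    grid = np.linspace(V_range[0], V_range[1], 281)
    vals = np.array([balance(V) for V in grid])
    sign_flips = np.where(np.sign(vals[:-1]) != np.sign(vals[1:]))[0]
    if sign_flips.size == 0:
        raise RuntimeError("no equilibrium found in the scanned V range")
    i = sign_flips[0]
    V_eq = brentq(balance, grid[i], grid[i + 1], xtol=1e-12)
    g = steady_state_gates(V_eq, rates, params)
    I_Ca = params.g_Ca * g.a_inf ** 2 * (V_eq - params.V_Ca)
    Ca_eq = params.Ca_rest - I_Ca * params.flux_conversion / max(
        params.gamma, 1e-12)
    k_inf, _ = sk_gate_kinetics(max(Ca_eq, 1e-12), params)
    b1, b2 = initial_bound_pools(params, scheme, Ca_eq)
    kw = dict(V=V_eq, h=g.h_inf, n1=g.n1_inf, n3=g.n3_inf, k=k_inf,
              Ca_i=Ca_eq)
    if scheme.kind == "pv":
        kw.update(PVCa_i=b1, PVMg_i=b2)
    elif scheme.kind in ("slow", "fast"):
        kw.update(BCa_i=b1)
    if not params.instantaneous_a:
        kw["a"] = g.a_inf
    return NeuronState(**kw)


def find_equilibrium(params: ModelParameters, scheme: BufferScheme,
                     I_app: float, guess: Optional[NeuronState] = None,
                     rates: Optional[RateCoefficientSet] = None,
                     tol: float = 1e-10, max_iter: int = 60
                     ) -> EquilibriumPoint:
    """Damped-Newton solution of rhs = 0 at fixed applied current.

    The Jacobian is by central finite differences (relative step 1e-6);
    eigenvalues of the reduced system (genuine dynamical variables only)
    are attached.  Raises on non-convergence.
    """
    rates = rates or default_rates()
    if guess is None:
        try:
            guess = _scalar_balance_state(params, scheme, I_app, rates)
        except RuntimeError:
            guess = default_initial_state(params, scheme)
    y_template = guess.to_array(scheme)
    idx, f = _reduced_system(params, scheme, I_app, rates, y_template)
    x = y_template[idx].copy()
    fx = np.asarray(f(x))
    converged = False
    for _ in range(max_iter):
        nrm = np.linalg.norm(fx)
        if nrm < tol:
            converged = True
            break
        J = _fd_jacobian(f, x)
        try:
            dx = np.linalg.solve(J, -fx)
        except np.linalg.LinAlgError:
            break
        lam = 1.0
        while lam > 1e-4:
            x_new = x + lam * dx
            f_new = np.asarray(f(x_new))
            if np.linalg.norm(f_new) < nrm:
                x, fx = x_new, f_new
                break
            lam *= 0.5
        else:
            break
    if not converged and np.linalg.norm(fx) > 1e-8:
        # damped Newton stalled (e.g. a stale warm start): restart from the
        # exact 1-D reduction of the equilibrium problem
        fresh = _scalar_balance_state(params, scheme, I_app, rates)
        y_template = fresh.to_array(scheme)
        idx, f = _reduced_system(params, scheme, I_app, rates, y_template)
        x = y_template[idx].copy()
        fx = np.asarray(f(x))
        for _ in range(max_iter):
            nrm = np.linalg.norm(fx)
            if nrm < tol:
                break
            J = _fd_jacobian(f, x)
            dx = np.linalg.solve(J, -fx)
            lam = 1.0
            while lam > 1e-4:
                x_new = x + lam * dx
                f_new = np.asarray(f(x_new))
                if np.linalg.norm(f_new) < nrm:
                    x, fx = x_new, f_new
                    break
                lam *= 0.5
            else:
                break
        if np.linalg.norm(fx) > 1e-8:
            raise RuntimeError(
                f"equilibrium solve did not converge at I_app = {I_app} pA "
                f"(residual {np.linalg.norm(fx):.2e})")
    J = _fd_jacobian(f, x)
    y = y_template.copy()
    y[idx] = x
    return EquilibriumPoint(
        I_app=I_app,
        state=NeuronState.from_array(y, scheme, params.instantaneous_a),
        y=y,
        eigenvalues=np.linalg.eigvals(J),
        residual_norm=float(np.linalg.norm(fx)),
    )


def continuation(params: ModelParameters, scheme: BufferScheme,
                 I_range: tuple, step: float = 1.0,
                 rates: Optional[RateCoefficientSet] = None,
                 guess: Optional[NeuronState] = None) -> list:
    """Natural-parameter continuation of the equilibrium branch.

    Sweeps I_app from I_range[0] to I_range[1] in increments of ``step``,
    warm-starting each solve from the previous solution.  Failed solves are
    reported as gaps (None entries trigger a warning), not silently skipped.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    I_lo, I_hi = I_range
    currents = np.arange(I_lo, I_hi + 0.5 * step, step)
    points = []
    prev = guess
    for I in currents:
        try:
            pt = find_equilibrium(params, scheme, float(I), prev, rates)
        except RuntimeError as err:
            warnings.warn(f"continuation gap at I_app = {I} pA: {err}",
                          RuntimeWarning)
            points.append(None)
            continue
        points.append(pt)
        prev = pt.state
    return points


def branch_frame(points: list) -> pd.DataFrame:
    """Tabulate a continuation branch (I_app, V_eq, max Re eig, stability)."""
    rows = []
    for pt in points:
        if pt is None:
            continue
        rows.append({"I_app_pA": pt.I_app, "V_eq_mV": pt.V,
                     "max_re_eig_per_ms": pt.max_real_eig,
                     "stable": pt.stable})
    return pd.DataFrame(rows)


def find_hopf(params: ModelParameters, scheme: BufferScheme,
              I_range: tuple, tol: float = 0.1,
              rates: Optional[RateCoefficientSet] = None) -> float:
    """Bisection for the stability change of the equilibrium branch.

    Locates the zero crossing of the maximal eigenvalue real part to within
    ``tol`` pA and asserts the critical eigenvalue pair is complex (a Hopf
    bifurcation rather than a fold).
    """
    lo, hi = float(I_range[0]), float(I_range[1])
    # warm-started walk along the branch to bracket the first stability flip
    step = max(tol, min(5.0, (hi - lo) / 4))
    pt_lo = find_equilibrium(params, scheme, lo, None, rates)
    s_lo = pt_lo.max_real_eig
    prev = pt_lo
    bracket = None
    I = lo
    while I < hi - 1e-12:
        I_next = min(I + step, hi)
        pt = find_equilibrium(params, scheme, I_next, prev.state, rates)
        if np.sign(pt.max_real_eig) != np.sign(s_lo):
            bracket = (prev, pt)
            break
        prev, I = pt, I_next
    if bracket is None:
        raise ValueError(
            f"no stability change in [{lo}, {hi}] pA "
            f"(max Re eig stays {np.sign(s_lo):+.0f})")
    (pt_a, pt_b) = bracket
    lo, hi = pt_a.I_app, pt_b.I_app
    guess = pt_a.state
    critical = pt_b
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        pt = find_equilibrium(params, scheme, mid, guess, rates)
        guess = pt.state
        if np.sign(pt.max_real_eig) == np.sign(s_lo):
            lo = mid
        else:
            hi = mid
            critical = pt
    lead = critical.eigenvalues[np.argmax(critical.eigenvalues.real)]
    if abs(lead.imag) < 1e-12:
        raise RuntimeError(
            "critical eigenvalue is real: stability change is a fold, "
            "not a Hopf bifurcation")
    return 0.5 * (lo + hi)


def bisect_onset(classify: Callable[[float], bool], lo: float, hi: float,
                 tol: float) -> tuple:
    """Generic bisection for the switching point of a boolean criterion.

    Requires classify(lo) False and classify(hi) True; returns the final
    (lo, hi) bracket of width <= tol.
    """
    if classify(lo):
        raise ValueError("criterion already true at the lower end")
    if not classify(hi):
        raise ValueError("criterion false across the whole range")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if classify(mid):
            hi = mid
        else:
            lo = mid
    return lo, hi


def find_oscillation_onset(params: ModelParameters, scheme: BufferScheme,
                           I_range: tuple = (45.0, 100.0), tol: float = 0.5,
                           settle_ms: float = 6000.0,
                           rates: Optional[RateCoefficientSet] = None,
                           min_spikes: int = 2) -> SimpleNamespace:
    """Onset of persistent large-amplitude spiking by simulation bisection.

    At each trial current the model is integrated for ``settle_ms`` from two
    initial conditions — a spiking state inherited from the upper end of the
    range and the near-equilibrium rest state — and classified as
    oscillating if at least ``min_spikes`` spikes occur in the final
    1000 ms.  The onset from the spiking-state initialisation estimates the
    saddle-node of limit cycles; the two thresholds bracket any bistable
    (hysteresis) window.
    """
    rest = equilibrate(params, scheme, rates=rates)
    high = integrate(rest, params, scheme,
                     Stimulus.hold(float(I_range[1]), settle_ms),
                     rates=rates).final_state()

    def classify_from(init):
        def classify(I):
            traj = integrate(init, params, scheme,
                             Stimulus.hold(float(I), settle_ms), rates=rates)
            spikes = detect_spikes(traj)
            last = spikes.in_window((settle_ms - 1000.0, settle_ms))
            return len(last) >= min_spikes
        return classify

    lo_s, hi_s = bisect_onset(classify_from(high), *map(float, I_range), tol)
    onset_spiking = 0.5 * (lo_s + hi_s)
    try:
        lo_r, hi_r = bisect_onset(classify_from(rest), *map(float, I_range),
                                  tol)
        onset_rest = 0.5 * (lo_r + hi_r)
    except ValueError:
        onset_rest = float("nan")
    return SimpleNamespace(I_osc_onset=onset_spiking,
                           bracket=(onset_spiking, onset_rest))


def bifurcation_report(params: ModelParameters, scheme: BufferScheme,
                       I_range: tuple = (0.0, 120.0), step: float = 1.0,
                       hopf_tol: float = 0.1, onset_tol: float = 0.5,
                       settle_ms: float = 6000.0,
                       rates: Optional[RateCoefficientSet] = None
                       ) -> SimpleNamespace:
    """Full Figure-1-style characterisation: branch table, Hopf current and
    oscillation onset with bistability bracket.

    The report's invariant I_HB <= I_osc_onset reflects the model's class-2
    structure (an unstable periodic branch between the Hopf and the onset of
    large-amplitude spiking).
    """
    points = continuation(params, scheme, I_range, step, rates)
    branch = branch_frame(points)
    flips = np.flatnonzero(np.diff(branch.stable.to_numpy().astype(int)))
    if flips.size == 0:
        raise RuntimeError("no stability change along the branch")
    i = flips[0]
    I_hb = find_hopf(params, scheme,
                     (branch.I_app_pA.iloc[i], branch.I_app_pA.iloc[i + 1]),
                     hopf_tol, rates)
    onset = find_oscillation_onset(
        params, scheme, (max(I_range[0], I_hb), I_range[1]),
        onset_tol, settle_ms, rates)
    return SimpleNamespace(I_HB=I_hb, I_osc_onset=onset.I_osc_onset,
                           bistability_bracket=onset.bracket, branch=branch)
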