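"""Model core: state space, gating kinetics, ionic currents and the full ODE
right-hand side of the FS interneuron model.

The membrane obeys charge conservation,

    C_m dV/dt = -(I_Na + I_Kv1 + I_Kv3 + I_Ca + I_SK + I_leak) + I_app,

with currents (positive outward, nS x mV = pA)

    I_Na   = g_Na  m_inf(V)^3 h (V - V_Na)
    I_Kv1  = g_Kv1 n1^4 (V - V_K)
    I_Kv3  = g_Kv3 n3^2 (V - V_K)
    I_SK   = g_SK  k^2  (V - V_K)
    I_Ca   = g_Ca  a_inf(V)^2 (V - V_Ca)
    I_leak = g_leak (V - V_leak)

The Na activation m and HVA Ca activation a are fast and slaved to their
steady-state curves; h, n1, n3 relax with voltage-dependent alpha/beta rates
(dx/dt = alpha (1-x) - beta x) loaded from the packaged rate-coefficient
file.  The SK gate k is voltage independent and driven by shell calcium:
k_inf = Ca/(K_SK + Ca), tau_k = 1/(k_on_sk Ca + k_off_sk).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from types import SimpleNamespace
from typing import Optional

import numpy as np

from . import _kernel
from ._kernel import NY, IV, IH, IN1, IN3, IK, IA, ICA, IB1, IB2
from .parameters import ModelParameters, BufferScheme
from .rates import RateCoefficientSet, default_rates

__all__ = [
    "NeuronState", "CurrentBreakdown", "steady_state_gates",
    "sk_gate_kinetics", "ionic_currents", "rhs", "make_rhs", "pack_params",
    "active_indices", "default_rates",
]


@dataclass(frozen=True)
class NeuronState:
    """Instantaneous value of every dynamical variable.

    Bound-buffer pools: ``PVCa_i``/``PVMg_i`` for the PV scheme, ``BCa_i``
    for single-site buffers; unused pools stay at 0.  ``a`` is only a state
    variable in the non-instantaneous-a model variant (None otherwise).
    """

    V: float
    h: float
    n1: float
    n3: float
    k: float
    Ca_i: float
    PVCa_i: float = 0.0
    PVMg_i: float = 0.0
    BCa_i: float = 0.0
    a: Optional[float] = None

    def validate(self, scheme: BufferScheme | None = None,
                 tol: float = 1e-6) -> "NeuronState":
        for name in ("h", "n1", "n3", "k"):
            x = getattr(self, name)
            if not (-tol <= x <= 1.0 + tol):
                raise ValueError(f"gate {name}={x} outside [0, 1]")
        if self.Ca_i <= 0:
            raise ValueError("Ca_i must be > 0")
        if min(self.PVCa_i, self.PVMg_i, self.BCa_i) < -tol:
            raise ValueError("bound buffer pools must be >= 0")
        if scheme is not None and scheme.kind != "none":
            bound = (self.PVCa_i + self.PVMg_i if scheme.kind == "pv"
                     else self.BCa_i)
            if bound > scheme.B_T * (1 + tol) + tol:
                raise ValueError("bound pools exceed total buffer")
        return self

    # ---- flat-vector conversion (kernel layout) -----------------------
    def to_array(self, scheme: BufferScheme) -> np.ndarray:
        y = np.zeros(NY)
        y[IV], y[IH], y[IN1], y[IN3], y[IK] = self.V, self.h, self.n1, self.n3, self.k
        y[IA] = self.a if self.a is not None else _kernel.a_inf(self.V)
        y[ICA] = self.Ca_i
        if scheme.kind == "pv":
            y[IB1], y[IB2] = self.PVCa_i, self.PVMg_i
        elif scheme.kind in ("slow", "fast"):
            y[IB1] = self.BCa_i
        return y

    @classmethod
    def from_array(cls, y: np.ndarray, scheme: BufferScheme,
                   instantaneous_a: bool = True) -> "NeuronState":
        kw = dict(V=y[IV], h=y[IH], n1=y[IN1], n3=y[IN3], k=y[IK], Ca_i=y[ICA])
        if scheme.kind == "pv":
            kw.update(PVCa_i=y[IB1], PVMg_i=y[IB2])
        elif scheme.kind in ("slow", "fast"):
            kw.update(BCa_i=y[IB1])
        if not instantaneous_a:
            kw["a"] = y[IA]
        return cls(**kw)

    def replace(self, **kw) -> "NeuronState":
        return replace(self, **kw)


@dataclass(frozen=True)
class CurrentBreakdown:
    """The six membrane currents (pA, positive outward)."""

    I_Na: float
    I_Kv1: float
    I_Kv3: float
    I_SK: float
    I_Ca: float
    I_leak: float

    @property
    def total(self) -> float:
        return (self.I_Na + self.I_Kv1 + self.I_Kv3 + self.I_SK
                + self.I_Ca + self.I_leak)


def pack_params(params: ModelParameters) -> np.ndarray:
    """Flatten :class:`ModelParameters` into the kernel parameter vector."""
    return np.array([
        params.C_m, params.g_Na, params.g_Kv1, params.g_Kv3, params.g_SK,
        params.g_Ca, params.g_leak, params.V_Na, params.V_K, params.V_Ca,
        params.V_leak, params.K_SK, params.k_on_sk, params.k_off_sk,
        params.gamma, params.d, params.A, params.Ca_rest, params.Mg_i,
        params.F, float(params.literal_tau_k), float(params.instantaneous_a),
    ])


def active_indices(params: ModelParameters, scheme: BufferScheme) -> np.ndarray:
    """Indices of the kernel state vector that are genuine dynamical
    variables under the given scheme/variant (used for Jacobians)."""
    idx = [IV, IH, IN1, IN3, IK]
    if not params.instantaneous_a:
        idx.append(IA)
    idx.append(ICA)
    if scheme.kind == "pv":
        idx += [IB1, IB2]
    elif scheme.kind in ("slow", "fast"):
        idx.append(IB1)
    return np.array(idx)


def steady_state_gates(V: float, rates: RateCoefficientSet | None = None,
                       params: ModelParameters | None = None) -> SimpleNamespace:
    """Steady-state activations and time constants of the voltage gates at V.

    Returns a namespace with m_inf, a_inf, h_inf, n1_inf, n3_inf (all in
    (0, 1)) and tau_h, tau_n1, tau_n3 (ms); x_inf = alpha/(alpha+beta),
    tau_x = 1/(alpha+beta).
    """
    if not np.isfinite(V):
        raise ValueError("V must be finite")
    rates = rates or default_rates()
    R = rates.kernel_array()
    vals = [_kernel.rate_eval(R[i, 0], R[i, 1], R[i, 2], R[i, 3], float(V))
            for i in range(8)]
    am, bm, ah, bh, an1, bn1, an3, bn3 = vals
    return SimpleNamespace(
        m_inf=am / (am + bm),
        a_inf=_kernel.a_inf(float(V)),
        h_inf=ah / (ah + bh),
        n1_inf=an1 / (an1 + bn1),
        n3_inf=an3 / (an3 + bn3),
        tau_h=1.0 / (ah + bh),
        tau_n1=1.0 / (an1 + bn1),
        tau_n3=1.0 / (an3 + bn3),
    )


def sk_gate_kinetics(Ca_i: float, params: ModelParameters | None = None
                     ) -> tuple[float, float]:
    """SK gate steady state and relaxation time at shell calcium Ca_i (uM).

    k_inf = Ca/(K_SK + Ca); tau_k = 1/(k_on_sk Ca + k_off_sk) ms (mass-action
    relaxation of the two-state binding scheme, with K_SK = k_off_sk/k_on_sk).
    With ``params.literal_tau_k`` the printed 1/(K_SK + Ca) form is used
    instead, its value read as ms.
    """
    params = params or ModelParameters()
    if Ca_i <= 0:
        raise ValueError("Ca_i must be > 0")
    k_inf = Ca_i / (params.K_SK + Ca_i)
    if params.literal_tau_k:
        tau_k = 1.0 / (params.K_SK + Ca_i)
    else:
        tau_k = 1.0 / (params.k_on_sk * Ca_i + params.k_off_sk)
    return k_inf, tau_k


def ionic_currents(state: NeuronState, params: ModelParameters | None = None,
                   rates: RateCoefficientSet | None = None) -> CurrentBreakdown:
    """Evaluate the six membrane currents at the given state (pA, outward)."""
    p = params or ModelParameters()
    g = steady_state_gates(state.V, rates, p)
    a = state.a if (state.a is not None and not p.instantaneous_a) else g.a_inf
    return CurrentBreakdown(
        I_Na=p.g_Na * g.m_inf ** 3 * state.h * (state.V - p.V_Na),
        I_Kv1=p.g_Kv1 * state.n1 ** 4 * (state.V - p.V_K),
        I_Kv3=p.g_Kv3 * state.n3 ** 2 * (state.V - p.V_K),
        I_SK=p.g_SK * state.k ** 2 * (state.V - p.V_K),
        I_Ca=p.g_Ca * a ** 2 * (state.V - p.V_Ca),
        I_leak=p.g_leak * (state.V - p.V_leak),
    )


def make_rhs(params: ModelParameters, scheme: BufferScheme, stim=None,
             rates: RateCoefficientSet | None = None):
    """Build a fast ``f(t, y) -> dy`` closure over pre-packed arrays.

    Suitable for scipy's adaptive integrators and for repeated evaluation in
    Newton/Jacobian loops; semantics identical to :func:`rhs`.
    """
    from .simulate import Stimulus  # local import to avoid a cycle

    P = pack_params(params)
    R = (rates or default_rates()).kernel_array()
    code, BUF = scheme.kernel_arrays()
    if stim is None:
        seg = np.zeros((0, 4))
    elif isinstance(stim, Stimulus):
        seg = stim.segments_array()
    else:
        hold = float(stim)
        seg = np.array([[-1.0e300, 1.0e300, hold, hold]])

    def f(t: float, y: np.ndarray) -> np.ndarray:
        dy = np.empty(NY)
        _kernel.derivs(float(t), np.asarray(y, dtype=float), P, R, code,
                       BUF, seg, dy)
        return dy

    return f


def rhs(t: float, y: np.ndarray, params: ModelParameters,
        scheme: BufferScheme, stim=None,
        rates: RateCoefficientSet | None = None) -> np.ndarray:
    """Full model right-hand side on the flat kernel state vector.

    ``stim`` may be None (0 pA), a float (constant hold) or a
    :class:`~fsneuron.simulate.Stimulus`.  The calcium/buffer components
    agree with :func:`fsneuron.buffering.calcium_derivatives` (asserted by
    the test suite).
    """
    return make_rhs(params, scheme, stim, rates)(t, y)
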