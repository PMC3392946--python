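"""Numba-compiled core: rate evaluation, the model right-hand side and the
fixed-step RK4 loop.

Everything here works on flat float64 arrays so the same compiled code backs
both the public ``rhs`` wrapper (used by the equilibrium/bifurcation tooling
and the adaptive reference integrator in the tests) and the production
integrator.

State vector layout (length 9)::

    y = [V, h, n1, n3, k, a, Ca, b1, b2]

``a`` is the HVA Ca activation gate; with the default instantaneous-a variant
its slot is inert (derivative 0) and a = a_inf(V) is used directly.  ``b1`` is
the Ca2+-bound buffer pool ([PVCa] or [BCa]); ``b2`` is the Mg2+-bound PV pool
(unused for single-site buffers).

Parameter vector layout (length 22)::

    [C_m, g_Na, g_Kv1, g_Kv3, g_SK, g_Ca, g_leak,
     V_Na, V_K, V_Ca, V_leak, K_SK, k_on_sk, k_off_sk,
     gamma, d, A, Ca_rest, Mg_i, F, literal_tau_k, instantaneous_a]

Rate coefficient array: (8, 4), rows (a_m, b_m, a_h, b_h, a_n1, b_n1,
a_n3, b_n3), columns (template code, C, V_half, s).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

NY = 9
IV, IH, IN1, IN3, IK, IA, ICA, IB1, IB2 = range(NY)

# HVA Ca activation steady state: a_inf = 1/(1 + exp((-6 - V)/7.775))
A_VHALF = -6.0
A_SLOPE = 7.775

SCHEME_NONE = 0
SCHEME_PV = 1
SCHEME_SINGLE = 2


@njit(cache=True)
def rate_eval(code: float, C: float, V_half: float, s: float, V: float) -> float:
    """Evaluate one rate template at V (mV) -> ms^-1."""
    if code == 0.0:  # linoid, analytic limit C*s at the singularity
        x = V - V_half
        if abs(x) < 1e-7:
            return C * s
        z = x / s
        if z > 700.0:
            z = 700.0
        elif z < -700.0:
            z = -700.0
        return C * x / (math.exp(z) - 1.0)
    elif code == 1.0:  # exponential
        return C * math.exp((V - V_half) / s)
    elif code == 2.0:  # sigmoid
        return C / (1.0 + math.exp(-(V - V_half) / s))
    else:  # constant
        return C


@njit(cache=True)
def a_inf(V: float) -> float:
    return 1.0 / (1.0 + math.exp((A_VHALF - V) / A_SLOPE))


@njit(cache=True)
def tau_a(V: float) -> float:
    """HVA Ca activation time constant (ms); only used by the
    non-instantaneous-a model variant.  alpha/beta parse of the source
    L-type scheme: alpha = 8.01/(1+exp(-0.072 (V-5))),
    beta = 0.1 (V+8.9)/(exp(0.2 (V+8.9)) - 1)."""
    alpha = 8.01 / (1.0 + math.exp(-0.072 * (V - 5.0)))
    x = V + 8.9
    if abs(x) < 1e-7:
        beta = 0.5  # 0.1/0.2, linoid limit
    else:
        beta = 0.1 * x / (math.exp(0.2 * x) - 1.0)
    return 1.0 / (alpha + beta)


@njit(cache=True)
def stim_eval(seg: np.ndarray, t: float) -> float:
    """Piecewise stimulus: seg rows are (t0, t1, I0, I1); linear in each
    segment, 0 pA outside all segments."""
    for i in range(seg.shape[0]):
        t0 = seg[i, 0]
        t1 = seg[i, 1]
        if t0 <= t < t1:
            I0 = seg[i, 2]
            I1 = seg[i, 3]
            if I0 == I1:
                return I0
            return I0 + (I1 - I0) * (t - t0) / (t1 - t0)
    # tolerate 1-ulp overshoot of the final segment end (RK4 substeps)
    if seg.shape[0] > 0 and abs(t - seg[-1, 1]) < 1e-9:
        return seg[-1, 3]
    return 0.0


@njit(cache=True)
def derivs(t: float, y: np.ndarray, P: np.ndarray, R: np.ndarray,
           scheme: int, BUF: np.ndarray, seg: np.ndarray,
           dy: np.ndarray) -> None:
    """Model right-hand side; writes dy in place (units per ms)."""
    V = y[IV]
    h = y[IH]
    n1 = y[IN1]
    n3 = y[IN3]
    k = y[IK]
    Ca = y[ICA]
    b1 = y[IB1]
    b2 = y[IB2]

    am = rate_eval(R[0, 0], R[0, 1], R[0, 2], R[0, 3], V)
    bm = rate_eval(R[1, 0], R[1, 1], R[1, 2], R[1, 3], V)
    ah = rate_eval(R[2, 0], R[2, 1], R[2, 2], R[2, 3], V)
    bh = rate_eval(R[3, 0], R[3, 1], R[3, 2], R[3, 3], V)
    an1 = rate_eval(R[4, 0], R[4, 1], R[4, 2], R[4, 3], V)
    bn1 = rate_eval(R[5, 0], R[5, 1], R[5, 2], R[5, 3], V)
    an3 = rate_eval(R[6, 0], R[6, 1], R[6, 2], R[6, 3], V)
    bn3 = rate_eval(R[7, 0], R[7, 1], R[7, 2], R[7, 3], V)

    m = am / (am + bm)  # instantaneous Na activation
    ainf = a_inf(V)
    if P[21] != 0.0:  # instantaneous a (default)
        a = ainf
        dy[IA] = 0.0
    else:
        a = y[IA]
        dy[IA] = (ainf - a) / tau_a(V)

    I_Na = P[1] * m * m * m * h * (V - P[7])
    I_Kv1 = P[2] * n1 * n1 * n1 * n1 * (V - P[8])
    I_Kv3 = P[3] * n3 * n3 * (V - P[8])
    I_SK = P[4] * k * k * (V - P[8])
    I_Ca = P[5] * a * a * (V - P[9])
    I_leak = P[6] * (V - P[10])
    I_app = stim_eval(seg, t)

    dy[IV] = (-(I_Na + I_Kv1 + I_Kv3 + I_SK + I_Ca + I_leak) + I_app) / P[0]
    dy[IH] = ah * (1.0 - h) - bh * h
    dy[IN1] = an1 * (1.0 - n1) - bn1 * n1
    dy[IN3] = an3 * (1.0 - n3) - bn3 * n3

    k_inf = Ca / (P[11] + Ca)
    if P[20] != 0.0:  # literal printed tau_k form, read as ms
        tau_k = 1.0 / (P[11] + Ca)
    else:  # mass-action relaxation time
        tau_k = 1.0 / (P[12] * Ca + P[13])
    dy[IK] = (k_inf - k) / tau_k

    # shell calcium balance: influx - clearance - net buffer uptake
    influx = -I_Ca * 1.0e6 / (2.0 * P[19] * P[16] * P[15])
    clearance = -P[14] * (Ca - P[17])
    if scheme == SCHEME_PV:
        free = BUF[0] - b1 - b2
        db1 = BUF[1] * Ca * free - BUF[2] * b1
        db2 = BUF[3] * P[18] * free - BUF[4] * b2
        dy[IB1] = db1
        dy[IB2] = db2
        dy[ICA] = influx + clearance - db1
    elif scheme == SCHEME_SINGLE:
        free = BUF[0] - b1
        db1 = BUF[1] * Ca * free - BUF[2] * b1
        dy[IB1] = db1
        dy[IB2] = 0.0
        dy[ICA] = influx + clearance - db1
    else:
        dy[IB1] = 0.0
        dy[IB2] = 0.0
        dy[ICA] = influx + clearance


@njit(cache=True)
def rk4_run(y0: np.ndarray, P: np.ndarray, R: np.ndarray, scheme: int,
            BUF: np.ndarray, seg: np.ndarray, dt: float, n_steps: int,
            stride: int):
    """Classic fixed-step RK4; records every ``stride`` steps (incl. t=0).

    Returns (recorded states (n_rec, NY), status).  status >= 0 flags the
    first recorded index at which the state went non-finite; -1 means clean.
    """
    n_rec = n_steps // stride + 1
    out = np.empty((n_rec, NY))
    y = y0.copy()
    k1 = np.empty(NY)
    k2 = np.empty(NY)
    k3 = np.empty(NY)
    k4 = np.empty(NY)
    yt = np.empty(NY)
    out[0] = y
    j = 1
    status = -1
    for step in range(n_steps):
        t = step * dt
        derivs(t, y, P, R, scheme, BUF, seg, k1)
        for i in range(NY):
            yt[i] = y[i] + 0.5 * dt * k1[i]
        derivs(t + 0.5 * dt, yt, P, R, scheme, BUF, seg, k2)
        for i in range(NY):
            yt[i] = y[i] + 0.5 * dt * k2[i]
        derivs(t + 0.5 * dt, yt, P, R, scheme, BUF, seg, k3)
        for i in range(NY):
            yt[i] = y[i] + dt * k3[i]
        derivs(t + dt, yt, P, R, scheme, BUF, seg, k4)
        for i in range(NY):
            y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        if (step + 1) % stride == 0:
            ok = True
            for i in range(NY):
                if not math.isfinite(y[i]):
                    ok = False
            out[j] = y
            if not ok and status < 0:
                status = j
            j += 1
    return out[:j], status


@njit(cache=True)
def gates_over(V: np.ndarray, R: np.ndarray):
    """Vectorised instantaneous gates m_inf(V), a_inf(V) over a trace."""
    n = V.shape[0]
    m = np.empty(n)
    a = np.empty(n)
    for i in range(n):
        am = rate_eval(R[0, 0], R[0, 1], R[0, 2], R[0, 3], V[i])
        bm = rate_eval(R[1, 0], R[1, 1], R[1, 2], R[1, 3], V[i])
        m[i] = am / (am + bm)
        a[i] = a_inf(V[i])
    return m, a
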