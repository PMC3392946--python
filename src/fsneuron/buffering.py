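"""Submembrane calcium shell balance and buffer kinetics.

Free calcium in a thin shell (thickness d) under the membrane obeys

    dCa/dt = -I_Ca/(2 F A d) - gamma (Ca - Ca_rest) - d[bound]/dt,

i.e. influx through the HVA Ca current (inward I_Ca < 0 raises Ca), linear
clearance toward the resting level, and net uptake by the buffer.  Units:
Ca in uM, time in ms, I_Ca in pA; with the default shell (A = 3000 um^2,
d = 0.2 um) the influx conversion is about 8.637e-3 uM ms^-1 per -1 pA.

Buffer schemes (see :class:`~fsneuron.parameters.BufferScheme`):

- PV: one mixed site per binding equivalent, competing mass-action binding of
  Ca2+ and Mg2+ ([Mg2+]_i held constant);
- slow/fast: a single Ca2+ site with k_off = k_on * K_D.

Only the Ca2+-bound flux enters the calcium balance; Mg2+ binding affects it
indirectly by occupying PV sites.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np

from .parameters import ModelParameters, BufferScheme

__all__ = ["calcium_derivatives", "equilibrium_occupancy", "buffering_capacity",
           "initial_bound_pools"]


def calcium_derivatives(state, I_Ca: float,
                        params: ModelParameters | None = None,
                        scheme: BufferScheme | None = None) -> SimpleNamespace:
    """Time derivatives of shell calcium and the bound-buffer pools (uM/ms).

    ``state`` needs attributes Ca_i and the pools relevant to ``scheme``
    (PVCa_i/PVMg_i or BCa_i).  Returns a namespace with dCa, and dPVCa/dPVMg
    or dBCa depending on the scheme.
    """
    p = params or ModelParameters()
    scheme = scheme if scheme is not None else BufferScheme.none()
    Ca = state.Ca_i
    influx = -I_Ca * p.flux_conversion
    clearance = -p.gamma * (Ca - p.Ca_rest)
    out = SimpleNamespace(dCa=influx + clearance)
    if scheme.kind == "pv":
        free = scheme.B_T - state.PVCa_i - state.PVMg_i
        if free < -1e-9 * max(scheme.B_T, 1.0):
            raise ValueError("negative free PV concentration (corrupt state)")
        out.dPVCa = scheme.k_on_ca * Ca * free - scheme.k_off_ca * state.PVCa_i
        out.dPVMg = scheme.k_on_mg * p.Mg_i * free - scheme.k_off_mg * state.PVMg_i
        out.dCa -= out.dPVCa  # Mg2+ binding does not consume Ca2+
    elif scheme.kind in ("slow", "fast"):
        free = scheme.B_T - state.BCa_i
        if free < -1e-9 * max(scheme.B_T, 1.0):
            raise ValueError("negative free buffer concentration (corrupt state)")
        out.dBCa = scheme.k_on * Ca * free - scheme.k_off * state.BCa_i
        out.dCa -= out.dBCa
    return out


def equilibrium_occupancy(Ca: float, Mg: float = 0.0,
                          scheme: BufferScheme | None = None) -> SimpleNamespace:
    """Equilibrium free/bound fractions of the buffer at fixed (Ca, Mg).

    For PV the single mixed site partitions competitively:
    free : Ca-bound : Mg-bound = 1 : Ca/K_D_ca : Mg/K_D_mg.  For single-site
    buffers bound = Ca/(Ca + K_D).  Fractions sum to 1; concentrations are
    the fractions scaled by B_T.
    """
    if Ca <= 0:
        raise ValueError("Ca must be > 0")
    if Mg < 0:
        raise ValueError("Mg must be >= 0")
    scheme = scheme if scheme is not None else BufferScheme.none()
    if scheme.kind == "none":
        return SimpleNamespace(free=1.0, bound_ca=0.0, bound_mg=0.0)
    if scheme.kind == "pv":
        w_free = 1.0
        w_ca = Ca / scheme.K_D_ca
        w_mg = Mg / scheme.K_D_mg
        z = w_free + w_ca + w_mg
        return SimpleNamespace(free=w_free / z, bound_ca=w_ca / z,
                               bound_mg=w_mg / z)
    bound = Ca / (Ca + scheme.K_D)
    return SimpleNamespace(free=1.0 - bound, bound_ca=bound, bound_mg=0.0)


def initial_bound_pools(params: ModelParameters, scheme: BufferScheme,
                        Ca: float | None = None) -> tuple[float, float]:
    """Bound pools (b1, b2) in uM at equilibrium with (Ca, Mg_i).

    Used to initialise states before burn-in; b1 is PVCa or BCa, b2 is PVMg.
    """
    Ca = params.Ca_rest if Ca is None else Ca
    occ = equilibrium_occupancy(Ca, params.Mg_i, scheme)
    return scheme.B_T * occ.bound_ca, scheme.B_T * occ.bound_mg


def buffering_capacity(Ca: float, scheme: BufferScheme) -> float:
    """Differential buffering ratio d[bound]/d[Ca] at equilibrium.

    For a single Ca2+ site this is B_T K_D/(Ca + K_D)^2; for PV the partial
    derivative of the competitive equilibrium at fixed Mg (Mg_i = 0 reduces
    to the single-site formula with K_D_ca).  Diagnostic only — the dynamics
    integrate the full kinetics.
    """
    if Ca <= 0:
        raise ValueError("Ca must be > 0")
    if scheme.kind == "none" or scheme.B_T == 0:
        return 0.0
    if scheme.kind == "pv":
        # d/dCa of B_T * (Ca/K_ca) / (1 + Ca/K_ca + Mg/K_mg) at fixed Mg = 0
        K = scheme.K_D_ca
    else:
        K = scheme.K_D
    return scheme.B_T * K / (Ca + K) ** 2
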