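"""Model parameters and buffering schemes for the striatal FS interneuron model.

The default :class:`ModelParameters` reproduce the reference parameter set of
the single-compartment fast-spiking (FS) interneuron model: six ionic currents
(Na, Kv1, Kv3, SK, high-voltage-activated Ca, leak) coupled to a thin
submembrane calcium shell with first-order clearance.  Concentrations are in
micromolar, time in milliseconds, voltages in millivolts, conductances in
nanosiemens and currents in picoamperes throughout the package (nS x mV = pA).

Buffering conditions are described by :class:`BufferScheme`:

``pv``
    Parvalbumin with mixed Ca2+/Mg2+ binding sites; Ca2+ binding is rate
    limited by the slow Mg2+ off-rate, which makes PV a slow buffer at rest.
``slow``
    Single-site Ca2+ buffer with EGTA-like kinetics (k_on = 0.01 uM^-1 ms^-1,
    K_D = 0.1 uM).
``fast``
    Single-site Ca2+ buffer with BAPTA-like kinetics, equivalent to the
    metal-free form of PV (k_on = 0.1 uM^-1 ms^-1, K_D = 0.01 uM).
``none``
    Unbuffered shell (influx and clearance only).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields, asdict, replace

import numpy as np
import yaml

__all__ = ["ModelParameters", "BufferScheme", "load_parameters", "FARADAY"]

#: Faraday constant, C mol^-1.
FARADAY = 96485.0


@dataclass(frozen=True)
class ModelParameters:
    """Biophysical parameters of the FS interneuron model.

    All defaults correspond to the reference parameter set: the passive
    properties give an input resistance of 1/g_leak = 400 MOhm and a resting
    potential near -70 mV; the SK gate rates satisfy K_SK = k_off_sk/k_on_sk
    = 0.5 uM.
    """

    C_m: float = 30.0          # membrane capacitance, pF
    g_Na: float = 700.0        # nS
    g_Kv1: float = 2.0         # nS
    g_Kv3: float = 300.0       # nS
    g_SK: float = 2.0          # nS
    g_Ca: float = 30.0         # nS
    g_leak: float = 2.5        # nS
    V_Na: float = 74.0         # mV
    V_K: float = -90.0         # mV
    V_Ca: float = 80.0         # mV
    V_leak: float = -68.0      # mV
    K_SK: float = 0.5          # SK half-activation Ca2+, uM
    k_on_sk: float = 0.4       # SK Ca2+ binding rate, uM^-1 ms^-1
    k_off_sk: float = 0.2      # SK Ca2+ unbinding rate, ms^-1
    gamma: float = 1.0         # Ca2+ clearance rate, ms^-1
    d: float = 0.2             # shell thickness, um
    A: float = 3000.0          # cell surface, um^2
    Ca_rest: float = 0.07      # resting free Ca2+, uM
    Mg_i: float = 500.0        # fixed intracellular Mg2+, uM
    F: float = FARADAY         # Faraday constant, C mol^-1
    # -- model variants (off by default) -------------------------------
    #: use the literal tau_k = 1/(K_SK + Ca) form (read in ms) instead of the
    #: mass-action relaxation time 1/(k_on_sk*Ca + k_off_sk).
    literal_tau_k: bool = False
    #: integrate the HVA Ca activation gate `a` with its voltage-dependent
    #: time constant instead of the (default) instantaneous a = a_inf(V).
    instantaneous_a: bool = True

    def __post_init__(self) -> None:
        for name in ("g_Na", "g_Kv1", "g_Kv3", "g_SK", "g_Ca", "g_leak"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        for name, cond in [
            ("C_m", self.C_m > 0),
            ("d", self.d > 0),
            ("A", self.A > 0),
            ("gamma", self.gamma >= 0),
            ("Ca_rest", self.Ca_rest > 0),
            ("k_on_sk", self.k_on_sk > 0),
            ("k_off_sk", self.k_off_sk > 0),
        ]:
            if not cond:
                raise ValueError(f"invalid value for {name}")

    @property
    def input_resistance_MOhm(self) -> float:
        """Passive input resistance 1/g_leak in megaohm (1/nS = GOhm)."""
        return 1.0e3 / self.g_leak

    @property
    def shell_volume_um3(self) -> float:
        """Volume of the submembrane shell, A*d in um^3."""
        return self.A * self.d

    @property
    def flux_conversion(self) -> float:
        """Conversion constant from -I_Ca (pA) to shell uM/ms.

        dCa/dt|influx = -I_Ca * 1e6 / (2 F A d); about 8.637e-3 uM ms^-1 pA^-1
        for the default shell geometry.
        """
        return 1.0e6 / (2.0 * self.F * self.A * self.d)

    def with_overrides(self, **overrides: float) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        valid = {f.name for f in fields(self)}
        unknown = set(overrides) - valid
        if unknown:
            raise KeyError(
                f"unknown parameter(s) {sorted(unknown)}; valid keys: {sorted(valid)}"
            )
        return replace(self, **overrides)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        """Short stable hash of the parameter values (for provenance)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


_PV_DEFAULTS = dict(k_on_ca=0.1, k_off_ca=0.001, k_on_mg=0.0008, k_off_mg=0.025)
_FAST_DEFAULTS = dict(k_on=0.1, K_D=0.01)
_SLOW_DEFAULTS = dict(k_on=0.01, K_D=0.1)

KINDS = ("none", "pv", "slow", "fast")


@dataclass(frozen=True)
class BufferScheme:
    """A calcium buffering condition.

    For ``pv`` the four mass-action rates of the mixed Ca2+/Mg2+ site are
    stored directly (uM^-1 ms^-1 for on-rates, ms^-1 for off-rates); affinities
    are derived, K_D = k_off/k_on.  For ``slow``/``fast`` the buffer is a
    single Ca2+ site parameterised by (k_on, K_D) with k_off = k_on * K_D.
    """

    kind: str = "pv"
    B_T: float = 0.0           # total buffer concentration, uM
    k_on_ca: float = _PV_DEFAULTS["k_on_ca"]
    k_off_ca: float = _PV_DEFAULTS["k_off_ca"]
    k_on_mg: float = _PV_DEFAULTS["k_on_mg"]
    k_off_mg: float = _PV_DEFAULTS["k_off_mg"]
    k_on: float = 0.0
    K_D: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown buffer kind {self.kind!r}; one of {KINDS}")
        if self.B_T < 0:
            raise ValueError("B_T must be >= 0")
        if self.kind == "pv":
            if min(self.k_on_ca, self.k_off_ca, self.k_on_mg, self.k_off_mg) <= 0:
                raise ValueError("PV rates must be > 0")
        elif self.kind in ("slow", "fast"):
            if self.k_on <= 0 or self.K_D <= 0:
                raise ValueError("single-site buffer requires k_on > 0 and K_D > 0")

    # ---- constructors -------------------------------------------------
    @classmethod
    def none(cls) -> "BufferScheme":
        return cls(kind="none", B_T=0.0)

    @classmethod
    def pv(cls, B_T: float, **rates: float) -> "BufferScheme":
        kw = dict(_PV_DEFAULTS)
        kw.update(rates)
        return cls(kind="pv", B_T=B_T, **kw)

    @classmethod
    def slow(cls, B_T: float, **rates: float) -> "BufferScheme":
        kw = dict(_SLOW_DEFAULTS)
        kw.update(rates)
        return cls(kind="slow", B_T=B_T, **kw)

    @classmethod
    def fast(cls, B_T: float, **rates: float) -> "BufferScheme":
        kw = dict(_FAST_DEFAULTS)
        kw.update(rates)
        return cls(kind="fast", B_T=B_T, **kw)

    @classmethod
    def make(cls, kind: str, B_T: float = 0.0, **rates: float) -> "BufferScheme":
        if kind == "none":
            return cls.none()
        return getattr(cls, kind)(B_T, **rates)

    # ---- derived quantities -------------------------------------------
    @property
    def k_off(self) -> float:
        """Single-site off-rate, k_on * K_D (ms^-1)."""
        return self.k_on * self.K_D

    @property
    def K_D_ca(self) -> float:
        """Ca2+ affinity (uM): k_off_ca/k_on_ca for PV, K_D otherwise."""
        if self.kind == "pv":
            return self.k_off_ca / self.k_on_ca
        return self.K_D

    @property
    def K_D_mg(self) -> float:
        """Mg2+ affinity of the PV site, k_off_mg/k_on_mg = 31.25 uM."""
        if self.kind != "pv":
            raise AttributeError("K_D_mg is defined for the PV scheme only")
        return self.k_off_mg / self.k_on_mg

    @property
    def n_bound_pools(self) -> int:
        return {"none": 0, "pv": 2, "slow": 1, "fast": 1}[self.kind]

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "B_T": self.B_T}
        if self.kind == "pv":
            d.update(
                k_on_ca=self.k_on_ca, k_off_ca=self.k_off_ca,
                k_on_mg=self.k_on_mg, k_off_mg=self.k_off_mg,
            )
        elif self.kind in ("slow", "fast"):
            d.update(k_on=self.k_on, K_D=self.K_D)
        return d

    # numeric encoding used by the integration kernel
    _KIND_CODES = {"none": 0, "pv": 1, "slow": 2, "fast": 2}

    def kernel_arrays(self) -> tuple[int, np.ndarray]:
        """Return (kind code, rate array) for the integration kernel.

        Rate array layout: [B_T, kon1, koff1, kon2, koff2]; slots 3-4 are the
        Mg2+ rates for PV and unused otherwise.
        """
        buf = np.zeros(5)
        buf[0] = self.B_T
        if self.kind == "pv":
            buf[1:] = [self.k_on_ca, self.k_off_ca, self.k_on_mg, self.k_off_mg]
        elif self.kind in ("slow", "fast"):
            buf[1] = self.k_on
            buf[2] = self.k_off
        return self._KIND_CODES[self.kind], buf


def load_parameters(path_or_text) -> ModelParameters:
    """Load :class:`ModelParameters` from a YAML/JSON mapping.

    Keys are the dataclass field names; any omitted key keeps its default.
    Unknown keys raise ``KeyError`` listing the valid names.
    """
    if hasattr(path_or_text, "read"):
        raw = path_or_text.read()
    else:
        text = str(path_or_text)
        if "\n" not in text and text.endswith((".yaml", ".yml", ".json")):
            with open(text) as fh:
                raw = fh.read()
        else:
            raw = text
    data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise TypeError("parameter file must contain a mapping")
    return ModelParameters().with_overrides(**data)
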