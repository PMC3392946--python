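"""Voltage-dependent gate rate coefficients, loaded from a data file.

The transient Na+, Kv1 and Kv3 gate kinetics of the model are treated as
*data*, not code: each alpha/beta rate is a parameterised template
(`linoid`, `exponential`, `sigmoid` or `constant`) whose coefficients ship in
``data/gate_rates.yaml`` together with their source citation.  Custom rate
files with the same structure can be substituted.

Rate templates (V in mV, result in ms^-1):

- ``linoid``:      C (V - V_half) / (exp((V - V_half)/s) - 1), with the
  analytic limit C*s at the removable singularity V = V_half
- ``exponential``: C exp((V - V_half)/s)
- ``sigmoid``:     C / (1 + exp(-(V - V_half)/s))
- ``constant``:    C
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

__all__ = ["RateFunction", "RateCoefficientSet", "load_rates", "default_rates",
           "TEMPLATES"]

TEMPLATES = ("linoid", "exponential", "sigmoid", "constant")
_TEMPLATE_CODES = {name: i for i, name in enumerate(TEMPLATES)}
GATES = ("m", "h", "n1", "n3")


@dataclass(frozen=True)
class RateFunction:
    """One alpha or beta rate: a template with coefficients (C, V_half, s)."""

    template: str
    C: float
    V_half: float = 0.0
    s: float = 1.0

    def __post_init__(self):
        if self.template not in TEMPLATES:
            raise ValueError(f"unknown template {self.template!r}")
        if self.template != "constant" and self.s == 0.0:
            raise ValueError("slope s must be nonzero")

    def __call__(self, V):
        """Evaluate the rate at V (mV, scalar or array) -> ms^-1."""
        V = np.asarray(V, dtype=float)
        if self.template == "linoid":
            x = V - self.V_half
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                out = np.where(
                    np.abs(x) < 1e-7,
                    self.C * self.s,
                    self.C * x / np.expm1(np.clip(x / self.s, -700, 700)),
                )
            return out if out.ndim else float(out)
        if self.template == "exponential":
            out = self.C * np.exp((V - self.V_half) / self.s)
        elif self.template == "sigmoid":
            out = self.C / (1.0 + np.exp(-(V - self.V_half) / self.s))
        else:
            out = np.full_like(V, self.C)
        return out if out.ndim else float(out)

    @property
    def code(self) -> int:
        return _TEMPLATE_CODES[self.template]

    def coefficients(self) -> np.ndarray:
        """Kernel encoding [template code, C, V_half, s]."""
        return np.array([float(self.code), self.C, self.V_half, self.s])


@dataclass(frozen=True)
class RateCoefficientSet:
    """Alpha/beta rate functions for the m, h, n1 and n3 gates."""

    alpha: dict
    beta: dict
    source: str = ""
    version: int = 0

    def __post_init__(self):
        for d in (self.alpha, self.beta):
            missing = set(GATES) - set(d)
            if missing:
                raise ValueError(f"missing gate rate(s): {sorted(missing)}")

    def validate(self, V_lo: float = -100.0, V_hi: float = 60.0, n: int = 321):
        """Check alpha, beta > 0 on a voltage grid (model sanity invariant)."""
        grid = np.linspace(V_lo, V_hi, n)
        for gate in GATES:
            for name, rate in (("alpha", self.alpha[gate]), ("beta", self.beta[gate])):
                vals = rate(grid)
                if not np.all(vals > 0):
                    raise ValueError(
                        f"{name}_{gate} is not strictly positive on "
                        f"[{V_lo}, {V_hi}] mV"
                    )
        return self

    def kernel_array(self) -> np.ndarray:
        """(8, 4) coefficient array, rows (a_m, b_m, a_h, b_h, a_n1, b_n1, a_n3, b_n3)."""
        rows = []
        for gate in GATES:
            rows.append(self.alpha[gate].coefficients())
            rows.append(self.beta[gate].coefficients())
        return np.asarray(rows)


def _parse_rate(entry: dict) -> RateFunction:
    return RateFunction(
        template=entry["template"],
        C=float(entry["C"]),
        V_half=float(entry.get("V_half", 0.0)),
        s=float(entry.get("s", 1.0)),
    )


def load_rates(path_or_text) -> RateCoefficientSet:
    """Load a :class:`RateCoefficientSet` from a YAML rate-coefficient file."""
    if hasattr(path_or_text, "read"):
        raw = path_or_text.read()
    else:
        text = str(path_or_text)
        if "\n" not in text:
            with open(text) as fh:
                raw = fh.read()
        else:
            raw = text
    data = yaml.safe_load(raw)
    gates = data["gates"]
    alpha = {g: _parse_rate(gates[g]["alpha"]) for g in gates}
    beta = {g: _parse_rate(gates[g]["beta"]) for g in gates}
    return RateCoefficientSet(
        alpha=alpha, beta=beta,
        source=data.get("source", ""), version=int(data.get("version", 0)),
    ).validate()


_DEFAULT = None


def default_rates() -> RateCoefficientSet:
    """The packaged gate kinetics (Erisir-type FS interneuron rates)."""
    global _DEFAULT
    if _DEFAULT is None:
        ref = resources.files("fsneuron") / "data" / "gate_rates.yaml"
        _DEFAULT = load_rates(ref.read_text())
    return _DEFAULT
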