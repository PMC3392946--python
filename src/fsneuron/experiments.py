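"""Config validation and registered experiment recipes.

Each recipe regenerates one quantitative figure-style analysis of the model
from a single call: the bifurcation diagram (``fig1``), step/ramp protocol
traces (``fig2``), calcium-envelope time courses (``fig3``), the
frequency-vs-concentration curves (``fig4``) and the plateau interspike
Ca/I_SK statistics (``fig5``).  Outputs are CSV/JSON files; summary keys are
stable identifiers (``mean_frequency_hz``, ``i_hb_pa``, ``ca_isi_min_um``,
``isk_isi_max_pa``, ...).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .analysis import (PLATEAU_PRESET_MS, detect_spikes, extract_envelopes,
                       frequency_vs_concentration, mean_frequency,
                       plateau_statistics, plateau_window,
                       run_plateau_protocol)
from .bifurcation import bifurcation_report
from .parameters import BufferScheme, KINDS, ModelParameters
from .simulate import BURN_IN_MS, DT_DEFAULT, build_protocol, equilibrate, \
    integrate

log = logging.getLogger("fsneuron")

__all__ = ["ExperimentSpec", "run_experiment", "validate_config", "RECIPES"]

#: low/high reference buffer concentrations (uM)
LOW_BT, HIGH_BT = 50.0, 1000.0
SWEEP_GRID = (0.0, 50.0, 250.0, 500.0, 1000.0, 1500.0)


@dataclass
class ExperimentSpec:
    """A named experiment with optional overrides."""

    name: str = "custom"
    overrides: dict = field(default_factory=dict)
    scheme: str = "pv"
    concentrations: tuple = (HIGH_BT,)
    amplitude: float = 100.0
    duration: float = 5000.0
    burn_in: float = BURN_IN_MS
    dt: float = DT_DEFAULT
    outdir: str = "fsneuron_out"

    def __post_init__(self):
        if self.name not in RECIPES:
            raise ValueError(
                f"unknown experiment {self.name!r}; one of {sorted(RECIPES)}")
        if self.scheme not in KINDS:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if len(self.concentrations) == 0:
            raise ValueError("concentration list must not be empty")

    def params(self) -> ModelParameters:
        return ModelParameters().with_overrides(**self.overrides)


_SPEC_KEYS = {f.name for f in dc_fields(ExperimentSpec)} - {"overrides"}
_SCHEME_KEYS = {"kind", "B_T", "k_on_ca", "k_off_ca", "k_on_mg", "k_off_mg",
                "k_on", "K_D"}


def validate_config(raw: str):
    """Parse a YAML/JSON config into (ModelParameters, BufferScheme,
    ExperimentSpec).

    Keys are routed by name: model-parameter fields go to
    :class:`ModelParameters` (missing ones take their defaults), scheme keys
    (``scheme``, ``B_T``, custom rates) to :class:`BufferScheme`, experiment
    keys to :class:`ExperimentSpec`.  Unknown keys are rejected with the
    list of valid names; the resolved configuration is echoed to the log.
    """
    data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise TypeError("config must be a mapping")
    param_keys = {f.name for f in dc_fields(ModelParameters)}
    p_kw, s_kw, e_kw = {}, {}, {}
    for key, val in data.items():
        if key in param_keys:
            p_kw[key] = val
        elif key == "scheme":
            s_kw["kind"] = val
        elif key in _SCHEME_KEYS:
            s_kw[key] = val
        elif key in _SPEC_KEYS:
            e_kw[key] = val
        else:
            valid = sorted(param_keys | _SCHEME_KEYS | _SPEC_KEYS
                           | {"scheme"})
            raise KeyError(f"unknown config key {key!r}; valid keys: {valid}")
    params = ModelParameters().with_overrides(**p_kw)
    kind = s_kw.pop("kind", "pv")
    bt = float(s_kw.pop("B_T", 0.0))
    scheme = BufferScheme.make(kind, bt, **s_kw)
    if "concentrations" in e_kw:
        e_kw["concentrations"] = tuple(e_kw["concentrations"])
    spec = ExperimentSpec(overrides=p_kw, scheme=kind, **e_kw)
    log.info("resolved config: params=%s scheme=%s spec=%s",
             params.to_dict(), scheme.to_dict(), spec)
    return params, scheme, spec


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _scheme_for(spec: ExperimentSpec, bt: float) -> BufferScheme:
    return BufferScheme.make(spec.scheme, bt) if bt > 0 else BufferScheme.none()


def _log_run(spec: ExperimentSpec, params: ModelParameters) -> None:
    log.info("experiment %s: params hash=%s dt=%s burn_in=%s version=%s",
             spec.name, params.hash(), spec.dt, spec.burn_in, _pkg_version)


# ---------------------------------------------------------------------------
# recipes
# ---------------------------------------------------------------------------

def _recipe_fig1(spec: ExperimentSpec, out: Path) -> dict:
    """Bifurcation diagram: equilibrium branch, Hopf and oscillation onset."""
    params = spec.params()
    scheme = _scheme_for(spec, spec.concentrations[0])
    rep = bifurcation_report(params, scheme)
    branch_path = out / "branch.csv"
    rep.branch.to_csv(branch_path, index=False)
    summary = {
        "i_hb_pa": rep.I_HB,
        "i_osc_onset_pa": rep.I_osc_onset,
        "bistability_bracket_pa": list(rep.bistability_bracket),
        "note": ("onset estimated by simulation bisection from a spiking "
                 "state; reported figure-caption and text values for these "
                 "currents differ by a few pA in the source literature"),
    }
    _write_json(out / "summary.json", summary)
    return {"files": [str(branch_path), str(out / "summary.json")],
            "summary": summary}


def _recipe_fig2(spec: ExperimentSpec, out: Path) -> dict:
    """1 s step (100 pA) and 1 s ramp (200 pA/s): traces + mean frequency."""
    params = spec.params()
    scheme = _scheme_for(spec, spec.concentrations[0])
    state = equilibrate(params, scheme, duration=spec.burn_in, dt=spec.dt)
    files, summary = [], {}
    step = build_protocol("step", spec.amplitude, 1000.0)
    traj = integrate(state, params, scheme, step, dt=spec.dt)
    traj.to_csv(out / "step_trace.csv")
    files.append(str(out / "step_trace.csv"))
    summary["mean_frequency_hz"] = mean_frequency(detect_spikes(traj))
    ramp = build_protocol("ramp", duration=1000.0, ramp_rate=200.0)
    traj_r = integrate(state, params, scheme, ramp, dt=spec.dt)
    traj_r.to_csv(out / "ramp_trace.csv")
    files.append(str(out / "ramp_trace.csv"))
    summary["ramp_spike_count"] = len(detect_spikes(traj_r))
    _write_json(out / "summary.json", summary)
    return {"files": files + [str(out / "summary.json")], "summary": summary}


def _recipe_fig3(spec: ExperimentSpec, out: Path) -> dict:
    """Envelope time courses and plateau attainment for the three schemes."""
    params = spec.params()
    files, summary = [], {}
    for kind in ("pv", "slow", "fast"):
        for bt in (LOW_BT, HIGH_BT):
            scheme = BufferScheme.make(kind, bt)
            traj, spikes = run_plateau_protocol(
                params, scheme, spec.amplitude, spec.duration, spec.burn_in,
                spec.dt)
            env = extract_envelopes(traj, spikes)
            name = f"envelope_{kind}_{int(bt)}.csv"
            env.to_csv(out / name, index=False)
            files.append(str(out / name))
            win = plateau_window(env)
            summary[f"plateau_onset_ms_{kind}_{int(bt)}"] = win.t_start
    _write_json(out / "summary.json", summary)
    return {"files": files + [str(out / "summary.json")], "summary": summary}


def _recipe_fig4(spec: ExperimentSpec, out: Path) -> dict:
    """Firing frequency vs buffer concentration for pv/slow/fast."""
    params = spec.params()
    tables = []
    for kind in ("pv", "slow", "fast"):
        tables.append(frequency_vs_concentration(
            params, kind, SWEEP_GRID, spec.amplitude, spec.duration,
            spec.burn_in, spec.dt))
    table = pd.concat(tables, ignore_index=True)
    path = out / "frequency_vs_concentration.csv"
    table.to_csv(path, index=False)
    summary = {
        "frequency_hz_bt0": float(
            table[(table.scheme == "pv") & (table.B_T_uM == 0)]
            .frequency_hz.iloc[0]),
        "frequency_hz_pv1500": float(
            table[(table.scheme == "pv") & (table.B_T_uM == 1500)]
            .frequency_hz.iloc[0]),
    }
    _write_json(out / "summary.json", summary)
    return {"files": [str(path), str(out / "summary.json")],
            "summary": summary}


def _recipe_fig5(spec: ExperimentSpec, out: Path) -> dict:
    """Plateau interspike Ca and I_SK statistics at low/high concentration."""
    params = spec.params()
    summary, files = {}, []
    for bt, tag in ((LOW_BT, "low"), (HIGH_BT, "high")):
        scheme = _scheme_for(spec, bt)
        traj, spikes = run_plateau_protocol(
            params, scheme, spec.amplitude, spec.duration, spec.burn_in,
            spec.dt)
        stats = plateau_statistics(traj, spikes, PLATEAU_PRESET_MS)
        summary.update({
            f"ca_isi_min_um_{tag}": stats.ca_min,
            f"ca_isi_max_um_{tag}": stats.ca_max,
            f"isk_isi_median_pa_{tag}": stats.isk_median,
            f"isk_isi_max_pa_{tag}": stats.isk_max,
            f"occupancy_{tag}": stats.occupancy,
            f"frequency_hz_{tag}": mean_frequency(detect_spikes(traj)),
        })
    _write_json(out / "summary.json", summary)
    return {"files": files + [str(out / "summary.json")], "summary": summary}


def _recipe_custom(spec: ExperimentSpec, out: Path) -> dict:
    """Sweep the configured scheme over the configured concentrations."""
    params = spec.params()
    table = frequency_vs_concentration(
        params, spec.scheme, spec.concentrations, spec.amplitude,
        spec.duration, spec.burn_in, spec.dt)
    path = out / "sweep.csv"
    table.to_csv(path, index=False)
    summary = {"frequency_hz": dict(
        zip(map(float, table.B_T_uM), map(float, table.frequency_hz)))}
    _write_json(out / "summary.json", summary)
    return {"files": [str(path), str(out / "summary.json")],
            "summary": summary}


RECIPES = {
    "fig1": _recipe_fig1,
    "fig2": _recipe_fig2,
    "fig3": _recipe_fig3,
    "fig4": _recipe_fig4,
    "fig5": _recipe_fig5,
    "custom": _recipe_custom,
}


def run_experiment(spec: ExperimentSpec) -> dict:
    """Run a registered recipe; returns a manifest of written files and the
    summary payload.  Fully deterministic."""
    out = Path(spec.outdir)
    out.mkdir(parents=True, exist_ok=True)
    params = spec.params()
    _log_run(spec, params)
    manifest = RECIPES[spec.name](spec, out)
    manifest["experiment"] = spec.name
    manifest["params_hash"] = params.hash()
    return manifest
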