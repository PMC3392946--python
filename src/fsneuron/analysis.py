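"""Spike-train and calcium-transient analysis.

Covers the quantities the model is interrogated for: mean firing frequency,
the lower/upper envelopes of the interspike calcium transients, buffer
occupancy, detection of the steady-state plateau, and the interspike SK
current that links residual calcium to spike-frequency adaptation.

Interspike conventions
----------------------
A spike time is the upward crossing of the detection threshold (default
0 mV), linearly interpolated between samples.  Calcium extrema are taken
over the open interval between successive spike times (which contains the
full action potential and its calcium transient).  SK-current statistics are
restricted to the *subthreshold* segment of each interval — from the AHP
trough (minimum of V) to the next spike — because the quantity of interest
is the SK current between action potentials, not during the spike itself
when the driving force is maximal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from types import SimpleNamespace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .parameters import ModelParameters, BufferScheme
from .rates import RateCoefficientSet
from .simulate import Trajectory, build_protocol, equilibrate, \
    integrate, DT_DEFAULT, STRIDE_DEFAULT, BURN_IN_MS

__all__ = ["SpikeTrain", "detect_spikes", "mean_frequency",
           "extract_envelopes", "plateau_window", "run_plateau_protocol",
           "frequency_vs_concentration", "PLATEAU_PRESET_MS"]

#: fixed steady-state plateau convention: 4th-5th second of the stimulus
PLATEAU_PRESET_MS = (4000.0, 5000.0)


@dataclass(frozen=True)
class SpikeTrain:
    """Detected spike times (ms) with their detection settings."""

    times: np.ndarray
    window: tuple
    threshold: float = 0.0
    refractory: float = 1.0

    def __len__(self) -> int:
        return len(self.times)

    def in_window(self, window: Optional[tuple] = None) -> np.ndarray:
        t0, t1 = window if window is not None else self.window
        return self.times[(self.times >= t0) & (self.times < t1)]


def detect_spikes(traj: Trajectory, threshold: float = 0.0,
                  refractory: float = 1.0) -> SpikeTrain:
    """Upward threshold crossings of V, with linear interpolation and a
    refractory guard (default 1 ms)."""
    V, t = traj.V, traj.t
    if len(t) == 0:
        raise ValueError("empty trajectory")
    idx = np.where((V[:-1] < threshold) & (V[1:] >= threshold))[0]
    times = []
    last = -np.inf
    for i in idx:
        frac = (threshold - V[i]) / (V[i + 1] - V[i])
        ts = t[i] + frac * (t[i + 1] - t[i])
        if ts - last >= refractory:
            times.append(ts)
            last = ts
    window = traj.stim.window or (t[0], t[-1])
    return SpikeTrain(times=np.asarray(times), window=window,
                      threshold=threshold, refractory=refractory)


def mean_frequency(spikes: SpikeTrain, window: Optional[tuple] = None,
                   method: str = "count") -> float:
    """Mean firing rate in Hz over a window (default: the stimulus window).

    ``count``: spikes in window / window duration (the convention that maps
    31 spikes in a 1 s step to 31 Hz).  ``isi``: (N-1)/(t_N - t_1) over the
    spikes in the window.
    """
    t0, t1 = window if window is not None else spikes.window
    if t1 <= t0:
        raise ValueError("zero-length window")
    inside = spikes.in_window((t0, t1))
    if method == "count":
        return len(inside) / (t1 - t0) * 1000.0
    if method == "isi":
        if len(inside) < 2:
            return 0.0
        return (len(inside) - 1) / (inside[-1] - inside[0]) * 1000.0
    raise ValueError(f"unknown method {method!r}")


def extract_envelopes(traj: Trajectory, spikes: SpikeTrain) -> pd.DataFrame:
    """Per-interspike-interval extrema of Ca and I_SK, plus buffer occupancy.

    One row per consecutive spike pair: interval bounds, Ca min/max over the
    open interval (lower/upper envelope values), I_SK min/max/median over
    the subthreshold (AHP-trough to next spike) segment, and the Ca2+
    occupancy of the buffer at the Ca minimum.
    """
    if len(spikes) < 2:
        raise ValueError("need at least 2 spikes to form interspike intervals")
    t = traj.t
    Ca = traj.Ca
    isk = traj.I_SK
    V = traj.V
    occ = traj.bound_fraction
    rows = []
    for a, b in zip(spikes.times[:-1], spikes.times[1:]):
        sel = np.where((t > a) & (t < b))[0]
        if sel.size == 0:
            continue
        ca_seg = Ca[sel]
        i_min = sel[np.argmin(ca_seg)]
        trough = sel[np.argmin(V[sel])]
        sub = sel[sel >= trough]
        rows.append({
            "t_start": a, "t_end": b,
            "ca_min": ca_seg.min(), "ca_max": ca_seg.max(),
            "isk_min": isk[sub].min(), "isk_max": isk[sub].max(),
            "isk_median": float(np.median(isk[sub])),
            "occupancy_at_ca_min": occ[i_min],
        })
    df = pd.DataFrame(rows)
    bad = df[df.ca_min > df.ca_max]
    assert bad.empty
    return df


def plateau_window(envelopes: pd.DataFrame, rel_tol: float = 0.01,
                   preset: tuple = PLATEAU_PRESET_MS) -> SimpleNamespace:
    """Earliest window from which the lower envelope is stationary.

    Finds the first interval index from which successive lower-envelope
    values (per-interval Ca minima) change by less than ``rel_tol``
    (relative) through the end of the train.  If no such index exists the
    fixed convention ``preset`` is returned with ``reached=False`` and a
    warning.
    """
    if envelopes.empty:
        raise ValueError("empty envelope sequence")
    lo = envelopes.ca_min.to_numpy()
    t0 = envelopes.t_start.to_numpy()
    rel = np.abs(np.diff(lo)) / np.maximum(lo[:-1], 1e-30)
    stable = rel < rel_tol
    # first index i such that all changes from i on are below tolerance
    onset = None
    run_ok = np.concatenate([np.cumprod(stable[::-1])[::-1], [1]]).astype(bool)
    hits = np.where(run_ok)[0]
    # the trailing single interval is trivially "stationary"; require the
    # plateau to span at least two intervals
    if hits.size and hits[0] < len(lo) - 1:
        onset = int(hits[0])
    if onset is None:
        warnings.warn("plateau never reached; falling back to the fixed "
                      f"{preset} ms window", RuntimeWarning)
        return SimpleNamespace(t_start=preset[0], t_end=preset[1],
                               reached=False, onset_index=None)
    return SimpleNamespace(t_start=float(t0[onset]),
                           t_end=float(envelopes.t_end.iloc[-1]),
                           reached=True, onset_index=onset)


def run_plateau_protocol(params: ModelParameters, scheme: BufferScheme,
                         amplitude: float = 100.0, duration: float = 5000.0,
                         burn_in: float = BURN_IN_MS, dt: float = DT_DEFAULT,
                         rates: Optional[RateCoefficientSet] = None,
                         record_stride: int = STRIDE_DEFAULT):
    """Burn-in then a step of ``amplitude`` pA for ``duration`` ms.

    Returns (trajectory, spike train) — the workhorse for the
    frequency/plateau analyses.
    """
    state = equilibrate(params, scheme, duration=burn_in, dt=dt, rates=rates)
    stim = build_protocol("step", amplitude, duration)
    traj = integrate(state, params, scheme, stim, dt=dt,
                     record_stride=record_stride, rates=rates)
    return traj, detect_spikes(traj)


def plateau_statistics(traj: Trajectory, spikes: SpikeTrain,
                       window: tuple = PLATEAU_PRESET_MS) -> SimpleNamespace:
    """Summary of the interspike Ca and I_SK over a plateau window.

    Means over the intervals fully inside ``window``: lower/upper envelope
    Ca (uM), subthreshold I_SK median/max (pA), occupancy at the Ca minima.
    """
    env = extract_envelopes(traj, spikes)
    sel = env[(env.t_start >= window[0]) & (env.t_end <= window[1])]
    if sel.empty:
        raise ValueError("no complete interspike interval inside the window")
    return SimpleNamespace(
        n_intervals=len(sel),
        ca_min=float(sel.ca_min.mean()),
        ca_max=float(sel.ca_max.mean()),
        isk_median=float(np.median(sel.isk_median)),
        isk_max=float(sel.isk_max.mean()),
        occupancy=float(sel.occupancy_at_ca_min.mean()),
    )


def frequency_vs_concentration(params: ModelParameters, scheme_kind: str,
                               concentrations: Sequence[float],
                               amplitude: float = 100.0,
                               duration: float = 5000.0,
                               burn_in: float = BURN_IN_MS,
                               dt: float = DT_DEFAULT,
                               rates: Optional[RateCoefficientSet] = None,
                               record_stride: int = STRIDE_DEFAULT
                               ) -> pd.DataFrame:
    """Mean firing frequency as a function of total buffer concentration.

    Runs one full burn-in + step simulation per concentration and measures
    the mean frequency over the whole stimulus window.  The expected
    monotone decrease with concentration is the model's central prediction
    and is asserted by the test suite, not here.
    """
    rows = []
    for bt in concentrations:
        if bt < 0:
            raise ValueError("concentrations must be >= 0")
        scheme = (BufferScheme.make(scheme_kind, bt) if bt > 0
                  else BufferScheme.none())
        traj, spikes = run_plateau_protocol(
            params, scheme, amplitude, duration, burn_in, dt, rates,
            record_stride)
        rows.append({"scheme": scheme_kind, "B_T_uM": bt,
                     "frequency_hz": mean_frequency(spikes)})
    return pd.DataFrame(rows)
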