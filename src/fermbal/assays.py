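"""Enzyme specific activities from spectrophotometric traces.

Activities follow the initial-rate convention: the steepest early linear
stretch of the trace is converted through Beer-Lambert into a volumetric
rate and normalised to protein,

    rate (mM/min)       = |dA/dt| / (extinction * path_length)
    specific activity   = rate / protein * 1000 / chromophores_per_turnover
                          [mU/mg = nmol substrate min^-1 mg^-1]

where ``chromophores_per_turnover`` is the number of monitored chromophore
molecules converted per substrate turnover (e.g. 2 methylviologen radicals
oxidised per fumarate reduced).  1 U = 1 umol substrate per minute;
consumption and production slopes both report positive activities.

Default optical contexts for the assays of interest are collected in
``ENZYME_PRESETS``; extinction coefficients are overridable, and the
ferredoxin-monitored PFOR assay requires a user-supplied delta-epsilon at
430 nm (no universal value exists for crude ferredoxin preparations).
The PFL activity is measured chemically (formate formed over time), not
optically, and has its own entry point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

__all__ = [
    "AssayTrace",
    "SpecificActivity",
    "ENZYME_PRESETS",
    "specific_activity_from_trace",
    "pfl_activity_from_formate",
]

#: per-enzyme optical defaults: wavelength (nm), extinction (mM^-1 cm^-1),
#: chromophores converted per substrate turnover.  None = must be supplied.
ENZYME_PRESETS: Dict[str, Dict[str, Optional[float]]] = {
    "ldh": {"wavelength": 340.0, "extinction": 6.22, "chromophores_per_turnover": 1.0},
    "mdh": {"wavelength": 340.0, "extinction": 6.22, "chromophores_per_turnover": 1.0},
    "frd": {"wavelength": 604.0, "extinction": 13.9, "chromophores_per_turnover": 2.0},
    "hyd": {"wavelength": 604.0, "extinction": 13.9, "chromophores_per_turnover": 2.0},
    "pfor": {"wavelength": 430.0, "extinction": None, "chromophores_per_turnover": None},
    "pfl": {"wavelength": None, "extinction": None, "chromophores_per_turnover": 1.0},
}


@dataclass
class AssayTrace:
    """An absorbance-versus-time trace with its cuvette context."""

    time: np.ndarray  # minutes, strictly increasing
    absorbance: np.ndarray  # AU
    wavelength: float = 340.0  # nm
    path_length: float = 0.2  # cm (anoxic glass cuvette)
    extinction: float = 6.22  # mM^-1 cm^-1 of the monitored chromophore
    electrons_per_turnover: float = 2.0
    chromophores_per_turnover: float = 1.0
    protein: float = 1.0  # mg per mL in the cuvette
    volume: float = 1.0  # mL

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.time.size != self.absorbance.size:
            raise ValueError("time and absorbance must have equal length")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if self.path_length <= 0:
            raise ValueError("path_length must be positive")
        if self.extinction <= 0:
            raise ValueError("extinction must be positive")
        if self.protein <= 0:
            raise ValueError("protein must be positive")


@dataclass
class SpecificActivity:
    value: float  # mU per mg protein
    linear_window: Tuple[float, float]  # minutes used for the slope
    r_squared: float
    slope: float = 0.0  # raw fitted slope (AU/min or mM/min)
    window_warning: bool = False


def _linfit(t: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Slope and r^2; a perfectly flat stretch counts as perfectly linear."""
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return float(slope), 1.0 if ss_res < 1e-30 else 0.0
    return float(slope), max(0.0, 1.0 - ss_res / ss_tot)


def _auto_linear_window(
    t: np.ndarray,
    y: np.ndarray,
    min_points: int = 4,
    r2_threshold: float = 0.99,
    nondecreasing: bool = False,
) -> Tuple[int, int, bool]:
    """Earliest window of >= ``min_points`` with r^2 >= threshold.

    Among windows sharing the earliest admissible start, the longest is
    taken.  Falls back to the whole trace (flagged) when nothing qualifies.
    """
    n = t.size
    for i in range(n - min_points + 1):
        best_j = None
        for j in range(i + min_points, n + 1):
            seg = y[i:j]
            if nondecreasing and np.any(np.diff(seg) < 0):
                break
            _, r2 = _linfit(t[i:j], seg)
            if r2 >= r2_threshold:
                best_j = j
        if best_j is not None:
            return i, best_j, False
    return 0, n, True


def specific_activity_from_trace(
    trace: AssayTrace,
    window: Optional[Tuple[float, float]] = None,
) -> SpecificActivity:
    """Specific activity (mU/mg) from an absorbance trace.

    ``window`` restricts the fit to ``(t_start, t_end)`` minutes; by default
    the earliest linear stretch (>= 4 points, r^2 >= 0.99) is used.
    """
    t, a = trace.time, trace.absorbance
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, a = t[mask], a[mask]
    if t.size < 3:
        raise ValueError("need at least 3 points in the fit window")
    warning = False
    if window is None and t.size >= 4:
        i, j, warning = _auto_linear_window(t, a)
        t, a = t[i:j], a[i:j]
    slope, r2 = _linfit(t, a)
    rate_mm_per_min = abs(slope) / (trace.extinction * trace.path_length)
    value = rate_mm_per_min / trace.protein * 1000.0 / trace.chromophores_per_turnover
    return SpecificActivity(
        value=float(value),
        linear_window=(float(t[0]), float(t[-1])),
        r_squared=r2,
        slope=slope,
        window_warning=warning,
    )


def pfl_activity_from_formate(
    time: np.ndarray,
    formate: np.ndarray,
    protein: float,
    window: Optional[Tuple[float, float]] = None,
) -> SpecificActivity:
    """Pyruvate-formate lyase activity from a formate formation series.

    ``time`` in minutes, ``formate`` in mM, ``protein`` in mg/mL.  The fitted
    window must be nondecreasing (formate is the reaction product); a window
    containing decreasing formate is rejected.
    """
    t = np.asarray(time, dtype=float)
    f = np.asarray(formate, dtype=float)
    if protein <= 0:
        raise ValueError("protein must be positive")
    if t.size != f.size or t.size < 3:
        raise ValueError("need matching series of at least 3 points")
    warning = False
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, f = t[mask], f[mask]
        if t.size < 3:
            raise ValueError("window contains fewer than 3 points")
        if np.any(np.diff(f) < 0):
            raise ValueError("formate decreases inside the requested window")
    elif t.size >= 4:
        i, j, warning = _auto_linear_window(t, f, nondecreasing=True)
        t, f = t[i:j], f[i:j]
    slope, r2 = _linfit(t, f)
    value = max(slope, 0.0) / protein * 1000.0
    return SpecificActivity(
        value=float(value),
        linear_window=(float(t[0]), float(t[-1])),
        r_squared=r2,
        slope=slope,
        window_warning=warning,
    )
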