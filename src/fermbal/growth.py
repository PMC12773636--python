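"""Exponential growth-rate estimation from OD600 time courses.

The specific growth rate mu (h^-1) is the slope of an ordinary least-squares
regression of ln(OD) on time over the exponential window.  When no window is
given, :func:`auto_window` picks the longest contiguous stretch of at least
four points whose log-linear fit reaches r^2 >= 0.995, breaking ties toward
the earlier window; when any stretch is numerically perfect (r^2 >=
1 - 1e-4, as noise-free data produces) only perfect stretches compete, so
exact exponentials are recovered exactly even when a plateau follows.  If no
stretch qualifies the fit falls back to the best four-point window and is
flagged.  No lag-, stationary- or death-phase model is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .timecourse import SummarySeries, TimeCourse, summarize

__all__ = ["GrowthFit", "fit_growth_rate", "fit_per_replicate", "auto_window"]


@dataclass
class GrowthFit:
    """Result of a log-linear growth fit."""

    mu: float  # specific growth rate, h^-1
    window: Tuple[float, float]  # (t_start, t_end) used for the fit, hours
    od_final: float  # maximum of the mean OD series
    r_squared: float
    n_points: int
    window_warning: bool = False  # True when auto-window fell back


def _loglinear(t: np.ndarray, od: np.ndarray) -> Tuple[float, float, float]:
    """Slope, intercept and r^2 of ln(od) ~ t.  r^2 of a constant series is 0."""
    y = np.log(od)
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return float(slope), float(intercept), 0.0
    return float(slope), float(intercept), max(0.0, 1.0 - ss_res / ss_tot)


def _coerce_series(series) -> Tuple[np.ndarray, np.ndarray]:
    if isinstance(series, TimeCourse):
        s = summarize(series, "od600")
        return s.time, s.mean
    if isinstance(series, SummarySeries):
        return series.time, series.mean
    time, od = series
    return np.asarray(time, dtype=float), np.asarray(od, dtype=float)


#: windows with r^2 above this compete among themselves: a numerically
#: perfect exponential stretch is never diluted by near-miss extensions
_PERFECT_R2 = 1.0 - 1e-4


def auto_window(
    series,
    r2_threshold: float = 0.995,
    min_points: int = 4,
) -> Tuple[float, float, bool]:
    """Select the exponential-phase window of an OD series.

    All contiguous windows of >= ``min_points`` strictly positive points are
    scored by the r^2 of their log-linear fit; the longest window at or
    above the threshold wins, ties broken toward the earlier start.  When
    any window is numerically perfect only perfect windows compete.
    Returns ``(t_start, t_end, fallback)``; ``fallback`` is True when no
    window qualified and the global best-r^2 window of length
    ``min_points`` was used instead.
    """
    time, od = _coerce_series(series)
    positive = od > 0
    if int(positive.sum()) < min_points:
        raise ValueError(f"need at least {min_points} strictly positive OD points")

    scored: list[Tuple[int, int, float]] = []
    best_fallback: Tuple[float, int] = (-np.inf, 0)
    n = time.size
    for i in range(n - min_points + 1):
        for j in range(i + min_points, n + 1):
            if not positive[i:j].all():
                continue
            _, _, r2 = _loglinear(time[i:j], od[i:j])
            if j - i == min_points and r2 > best_fallback[0]:
                best_fallback = (r2, i)
            if r2 >= r2_threshold:
                scored.append((i, j, r2))
    if scored:
        if any(r2 >= _PERFECT_R2 for _, _, r2 in scored):
            scored = [w for w in scored if w[2] >= _PERFECT_R2]
        i, j, _ = max(scored, key=lambda w: (w[1] - w[0], -w[0]))
        return float(time[i]), float(time[j - 1]), False
    i = best_fallback[1]
    return float(time[i]), float(time[i + min_points - 1]), True


def fit_growth_rate(
    series,
    window: Optional[Tuple[float, float]] = None,
    r2_threshold: float = 0.995,
    min_points: int = 4,
) -> GrowthFit:
    """Estimate mu by log-linear least squares on a mean OD series.

    ``series`` may be a :class:`~fermbal.timecourse.TimeCourse` (its mean
    od600 is used), a :class:`~fermbal.timecourse.SummarySeries`, or a
    ``(time, od)`` pair.  With ``window=None`` the exponential phase is
    detected automatically (three-point series are fitted whole).
    """
    time, od = _coerce_series(series)
    if time.size < 3:
        raise ValueError("need at least 3 OD points")
    od_final = float(np.nanmax(od))

    warning = False
    if window is None:
        if time.size == 3:
            window = (float(time[0]), float(time[-1]))
        else:
            t0, t1, warning = auto_window((time, od), r2_threshold, min_points)
            window = (t0, t1)
    mask = (time >= window[0]) & (time <= window[1])
    t_w, od_w = time[mask], od[mask]
    if t_w.size < 3:
        raise ValueError(f"window {window} contains fewer than 3 points")
    if np.any(od_w <= 0):
        raise ValueError(f"non-positive OD inside fit window {window}")
    slope, _, r2 = _loglinear(t_w, od_w)
    return GrowthFit(
        mu=slope,
        window=(float(t_w[0]), float(t_w[-1])),
        od_final=od_final,
        r_squared=r2,
        n_points=int(t_w.size),
        window_warning=warning,
    )


def fit_per_replicate(
    tc: TimeCourse,
    window: Optional[Tuple[float, float]] = None,
    **kwargs,
) -> Tuple[float, float, Sequence[GrowthFit]]:
    """Fit each OD replicate separately; returns (mean mu, SEM of mu, fits).

    Offered as the companion to the default mean-series fit when a
    replicate-level uncertainty on mu is wanted.
    """
    od = tc.od600
    if od is None:
        raise KeyError("time course has no od600 channel")
    fits = [fit_growth_rate((tc.time, od[k]), window=window, **kwargs) for k in range(od.shape[0])]
    mus = np.array([f.mu for f in fits])
    sem = float(np.std(mus, ddof=1) / np.sqrt(mus.size)) if mus.size > 1 else 0.0
    return float(mus.mean()), sem, fits
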