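"""Replicated growth / metabolite time-course tables.

The on-disk layout is a wide CSV: one ``time`` column (hours), then one
column per channel and replicate named ``<channel>_rep<k>`` (a bare channel
name is accepted as a single replicate).  This keeps replicated series
loss-free in a format any spreadsheet or plotting tool can open.

Replicate summaries follow the mean +/- SEM convention of the experiments
being emulated (N = 3 biological replicates): SEM uses the sample (n-1)
standard deviation divided by sqrt(n).  Missing values are allowed and are
ignored per timepoint, which accommodates sparse gas sampling.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from .compounds import DEFAULT_REGISTRY, CompoundRegistry

__all__ = [
    "TimeCourse",
    "SummarySeries",
    "TimeCourseError",
    "read_timecourse",
    "write_timecourse",
    "summarize",
]

_REP_PATTERN = re.compile(r"^(?P<channel>.+)_rep(?P<rep>\d+)$")


class TimeCourseError(ValueError):
    """Structured parse/validation error naming the offending row/column."""

    def __init__(self, message: str, column: Optional[str] = None, row: Optional[int] = None):
        detail = message
        if column is not None:
            detail += f" (column {column!r}"
            detail += f", row {row})" if row is not None else ")"
        elif row is not None:
            detail += f" (row {row})"
        super().__init__(detail)
        self.column = column
        self.row = row


@dataclass
class TimeCourse:
    """Replicated OD600 and metabolite concentration series on one time grid.

    ``channels`` maps channel name (``od600`` or a registered compound) to a
    float array of shape ``(replicates, timepoints)``; NaN marks a missing
    measurement.
    """

    time: np.ndarray
    channels: Dict[str, np.ndarray]
    condition: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or self.time.size < 1:
            raise TimeCourseError("time grid must be a non-empty 1-D array")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise TimeCourseError("time must be strictly increasing", column="time")
        cleaned = {}
        for name, values in self.channels.items():
            arr = np.atleast_2d(np.asarray(values, dtype=float))
            if arr.shape[1] != self.time.size:
                raise TimeCourseError(
                    f"channel {name!r} has {arr.shape[1]} timepoints, expected {self.time.size}",
                    column=name,
                )
            bad = np.argwhere(arr < 0)
            if bad.size:
                rep, idx = bad[0]
                raise TimeCourseError(
                    f"negative value {arr[rep, idx]:g}", column=f"{name}_rep{rep + 1}", row=int(idx)
                )
            cleaned[name] = arr
        self.channels = cleaned

    @property
    def replicate_count(self) -> int:
        return max((arr.shape[0] for arr in self.channels.values()), default=1)

    @property
    def concentrations(self) -> Dict[str, np.ndarray]:
        """Metabolite channels only (everything except od600)."""
        return {k: v for k, v in self.channels.items() if k != "od600"}

    @property
    def od600(self) -> Optional[np.ndarray]:
        return self.channels.get("od600")

    def validate_registry(self, registry: CompoundRegistry = DEFAULT_REGISTRY) -> None:
        unknown = [name for name in self.concentrations if name not in registry]
        if unknown:
            raise TimeCourseError(f"unregistered metabolite channels: {unknown}")

    def mean(self, channel: str) -> np.ndarray:
        return summarize(self, channel).mean


@dataclass
class SummarySeries:
    """Per-timepoint mean and standard error of a replicated channel."""

    time: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    channel: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)


def summarize(tc: TimeCourse, channel: str) -> SummarySeries:
    """Mean and SEM (sample SD / sqrt(n)) per timepoint for one channel.

    Missing replicate values are dropped per timepoint; a timepoint with a
    single remaining replicate reports SEM 0.
    """
    if channel not in tc.channels:
        raise KeyError(f"unknown channel {channel!r}; available: {sorted(tc.channels)}")
    values = tc.channels[channel]
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN / ddof slices
        mean = np.nanmean(values, axis=0)
        n = np.sum(~np.isnan(values), axis=0)
        sd = np.where(n > 1, np.nanstd(values, axis=0, ddof=1), 0.0)
    sem = np.where(n > 0, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return SummarySeries(tc.time, mean, sem, channel=channel)


def read_timecourse(
    path,
    sep: str = ",",
    registry: Optional[CompoundRegistry] = DEFAULT_REGISTRY,
    condition: str = "",
) -> TimeCourse:
    """Read a wide-layout CSV/TSV time course.

    Pass ``registry=None`` to skip checking channel names against the
    compound registry (od600 is always exempt).
    """
    frame = pd.read_csv(path, sep=sep)
    time_col = next((c for c in frame.columns if c.strip().lower() == "time"), None)
    if time_col is None:
        raise TimeCourseError(f"no time column found in {path}", column="time")
    time = frame[time_col].to_numpy(dtype=float)
    if time.size > 1 and not np.all(np.diff(time) > 0):
        bad = int(np.argmax(np.diff(time) <= 0)) + 1
        raise TimeCourseError("time not strictly increasing", column=time_col, row=bad)

    grouped: Dict[str, Dict[int, np.ndarray]] = {}
    for col in frame.columns:
        if col == time_col:
            continue
        m = _REP_PATTERN.match(col.strip())
        if m:
            name, rep = m.group("channel"), int(m.group("rep"))
        else:
            name, rep = col.strip(), 1
        try:
            values = frame[col].to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise TimeCourseError(f"non-numeric data: {exc}", column=col) from None
        neg = np.where(values < 0)[0]
        if neg.size:
            raise TimeCourseError(f"negative value {values[neg[0]]:g}", column=col, row=int(neg[0]))
        grouped.setdefault(name, {})[rep] = values

    channels = {}
    for name, reps in grouped.items():
        ordered = [reps[k] for k in sorted(reps)]
        channels[name] = np.vstack(ordered)
    tc = TimeCourse(time=time, channels=channels, condition=condition)
    if registry is not None:
        tc.validate_registry(registry)
    return tc


def write_timecourse(tc: TimeCourse, path, sep: str = ",", float_format: str = "%.6g") -> None:
    """Write the wide-layout CSV/TSV; inverse of :func:`read_timecourse`."""
    data: Dict[str, np.ndarray] = {"time": tc.time}
    for name, values in tc.channels.items():
        if values.shape[0] == 1:
            data[name] = values[0]
        else:
            for k in range(values.shape[0]):
                data[f"{name}_rep{k + 1}"] = values[k]
    pd.DataFrame(data).to_csv(path, sep=sep, index=False, float_format=float_format)
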