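"""Sensor-log and annotation I/O.

The raw material of the pipeline is a 5 Hz triaxial acceleration stream
exported by the logger as CSV, one row per sample, with the collection time
split across a date column and a time-of-day column carrying hundredths of
a second.  Accelerations are in gravitational units (g), so the static
component of the signal is a unit-magnitude gravity vector whose direction
in the sensor frame encodes the animal's posture.

Traces are plain :class:`pandas.DataFrame` objects with columns
``time`` (datetime64), ``x``, ``y``, ``z`` and, once labels are attached,
``posture`` and ``behavior``.  Samples the observers could not assign to a
single posture or behavior carry the sentinel label ``"ambiguous"`` and are
removed before windowing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sampling interval of the logger, seconds.
SAMPLE_PERIOD_S = 0.2
#: Sampling rate, Hz.
SAMPLE_RATE_HZ = 5.0

#: Posture ethogram: standing, right sternal recumbency, left sternal recumbency.
POSTURES = ("S", "RSR", "LSR")
#: Behavior ethogram.
BEHAVIORS = ("feeding", "moving", "resting", "ruminating", "standing_still")
#: Sentinel for samples without a univocal label.
AMBIGUOUS = "ambiguous"

TRACE_COLUMNS = ("time", "x", "y", "z")


class SensorCsvError(ValueError):
    """Malformed sensor CSV (bad row, bad timestamp order, missing column)."""


@dataclass
class CsvDialect:
    """Column layout of a sensor CSV export.

    The logger software's exact export layout is configurable here; the
    defaults define the dialect used throughout this package's fixtures:
    comma separator, dot decimal mark, ISO date, time with hundredths.
    """

    sep: str = ","
    decimal: str = "."
    date_col: str = "date"
    time_col: str = "time"
    x_col: str = "X"
    y_col: str = "Y"
    z_col: str = "Z"
    date_format: str = "%Y-%m-%d"
    time_format: str = "%H:%M:%S.%f"
    float_format: str = "%.6f"


@dataclass(frozen=True)
class AnnotationInterval:
    """Observer annotation over a half-open time interval [start, end)."""

    start: pd.Timestamp
    end: pd.Timestamp
    posture: str = AMBIGUOUS
    behavior: str = AMBIGUOUS

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"interval start {self.start} is not before end {self.end}")
        if self.posture not in POSTURES + (AMBIGUOUS,):
            raise ValueError(f"unknown posture label {self.posture!r}")
        if self.behavior not in BEHAVIORS + (AMBIGUOUS,):
            raise ValueError(f"unknown behavior label {self.behavior!r}")


@dataclass
class RemovalReport:
    """Bookkeeping for ambiguous-sample removal, one session.

    Mirrors the per-cow accounting columns: totals, removed and retained
    sample counts, and the corresponding minutes at 5 Hz.
    """

    total: int
    removed: int
    retained: int
    minutes_removed: float = field(init=False)
    minutes_retained: float = field(init=False)

    def __post_init__(self) -> None:
        if self.removed + self.retained != self.total:
            raise ValueError("removed + retained must equal total")
        self.minutes_removed = minutes_of(self.removed)
        self.minutes_retained = minutes_of(self.retained)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "total_observations": self.total,
                    "removed_observations": self.removed,
                    "used_observations": self.retained,
                    "minutes_removed": self.minutes_removed,
                    "minutes_used": self.minutes_retained,
                }
            ]
        )


def minutes_of(n_samples: int) -> float:
    """Duration in minutes of ``n_samples`` consecutive 5 Hz samples."""
    return n_samples * SAMPLE_PERIOD_S / 60.0


def _check_monotonic(times: pd.Series) -> None:
    diffs = times.diff().iloc[1:]
    bad = diffs <= pd.Timedelta(0)
    if bad.any():
        idx = int(np.argmax(bad.to_numpy()))
        raise SensorCsvError(
            f"timestamps not strictly increasing: first offending sample index {idx + 1}"
        )


def read_sensor_csv(path, dialect: CsvDialect | None = None) -> pd.DataFrame:
    """Read a sensor CSV export into an (unlabeled) trace.

    Parameters
    ----------
    path
        CSV file with per-row date, time-with-hundredths, X, Y, Z columns.
    dialect
        Column layout; defaults to the package dialect.

    Returns
    -------
    DataFrame with columns ``time, x, y, z`` in file order.

    Raises
    ------
    SensorCsvError
        If a row is malformed (the error names the file line) or the
        timestamps are not strictly increasing.
    """
    d = dialect or CsvDialect()
    raw = pd.read_csv(path, sep=d.sep, decimal=d.decimal, dtype=str, skipinitialspace=True)
    needed = [d.date_col, d.time_col, d.x_col, d.y_col, d.z_col]
    missing = [c for c in needed if c not in raw.columns]
    if missing:
        raise SensorCsvError(f"missing columns {missing}; found {list(raw.columns)}")

    axes = {}
    for col, out in ((d.x_col, "x"), (d.y_col, "y"), (d.z_col, "z")):
        vals = pd.to_numeric(raw[col].str.replace(d.decimal, ".", regex=False), errors="coerce")
        if vals.isna().any():
            # +2: header line plus 1-based numbering
            line = int(vals.index[vals.isna()][0]) + 2
            raise SensorCsvError(f"malformed value in column {col!r} at line {line}")
        axes[out] = vals.to_numpy(float)

    stamp = raw[d.date_col].str.strip() + " " + raw[d.time_col].str.strip()
    times = pd.to_datetime(stamp, format=f"{d.date_format} {d.time_format}", errors="coerce")
    if times.isna().any():
        line = int(times.index[times.isna()][0]) + 2
        raise SensorCsvError(f"malformed timestamp at line {line}")
    _check_monotonic(times)

    return pd.DataFrame({"time": times.to_numpy(), **axes})


def write_sensor_csv(trace: pd.DataFrame, path, dialect: CsvDialect | None = None) -> None:
    """Write a trace back out in the sensor CSV dialect (inverse of read)."""
    d = dialect or CsvDialect()
    t = pd.DatetimeIndex(trace["time"])
    out = pd.DataFrame(
        {
            d.date_col: t.strftime(d.date_format),
            # hundredths of a second: trim %f microseconds to 2 digits
            d.time_col: t.strftime(d.time_format).str[:-4],
            d.x_col: trace["x"].to_numpy(),
            d.y_col: trace["y"].to_numpy(),
            d.z_col: trace["z"].to_numpy(),
        }
    )
    out.to_csv(path, sep=d.sep, decimal=d.decimal, index=False, float_format=d.float_format)


def read_annotations(path) -> list[AnnotationInterval]:
    """Read observer intervals from a CSV with columns start,end,posture,behavior."""
    df = pd.read_csv(path)
    return [
        AnnotationInterval(
            start=pd.Timestamp(r.start),
            end=pd.Timestamp(r.end),
            posture=str(r.posture),
            behavior=str(r.behavior),
        )
        for r in df.itertuples()
    ]


def write_annotations(intervals: Iterable[AnnotationInterval], path) -> None:
    pd.DataFrame(
        [
            {"start": iv.start, "end": iv.end, "posture": iv.posture, "behavior": iv.behavior}
            for iv in intervals
        ]
    ).to_csv(path, index=False)


def _check_non_overlapping(intervals: Sequence[AnnotationInterval]) -> list[AnnotationInterval]:
    ivs = sorted(intervals, key=lambda iv: iv.start)
    for a, b in zip(ivs, ivs[1:]):
        if b.start < a.end:
            raise ValueError(f"overlapping annotation intervals: [{a.start}, {a.end}) and [{b.start}, {b.end})")
    return ivs


def apply_annotations(
    trace: pd.DataFrame, intervals: Sequence[AnnotationInterval]
) -> pd.DataFrame:
    """Attach posture/behavior labels to every sample of a trace.

    Each sample takes the labels of the (unique) half-open interval
    [start, end) covering its timestamp; samples covered by no interval
    are labeled ambiguous, the same category as observer-flagged
    non-univocal observations.
    """
    ivs = _check_non_overlapping(intervals)
    t = trace["time"].to_numpy()
    starts = np.array([iv.start.to_datetime64() for iv in ivs])
    ends = np.array([iv.end.to_datetime64() for iv in ivs])

    posture = np.full(len(trace), AMBIGUOUS, dtype=object)
    behavior = np.full(len(trace), AMBIGUOUS, dtype=object)
    # index of the last interval whose start <= t
    idx = np.searchsorted(starts, t, side="right") - 1
    valid = idx >= 0
    covered = np.zeros(len(trace), bool)
    covered[valid] = t[valid] < ends[idx[valid]]
    for k, iv in enumerate(ivs):
        sel = covered & (idx == k)
        posture[sel] = iv.posture
        behavior[sel] = iv.behavior

    out = trace.copy()
    out["posture"] = posture
    out["behavior"] = behavior
    return out


def drop_ambiguous(trace: pd.DataFrame, mode: str) -> tuple[pd.DataFrame, RemovalReport]:
    """Remove samples without a univocal label for the requested mode.

    Parameters
    ----------
    trace
        Labeled trace.
    mode
        ``"posture"`` or ``"behavior"`` — which label column must be
        univocal for a sample to be retained.

    Returns
    -------
    (retained trace in original order, removal report)
    """
    if mode not in ("posture", "behavior"):
        raise ValueError(f"mode must be 'posture' or 'behavior', got {mode!r}")
    if mode not in trace.columns:
        raise ValueError(f"trace has no {mode!r} label column; apply annotations first")
    keep = trace[mode].to_numpy() != AMBIGUOUS
    kept = trace.loc[keep].reset_index(drop=True)
    report = RemovalReport(total=len(trace), removed=int((~keep).sum()), retained=int(keep.sum()))
    return kept, report
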