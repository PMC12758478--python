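"""Interval segmentation and per-interval heart-rate / PVC-rate metrics.

A record is cut into consecutive half-open windows of fixed nominal
duration (1 hour, 10 minutes, or 1 minute).  For each window we report the
mean heart rate, the PVC count, and the PVC count scaled to the expected
number of PVCs in one hour — the X and Y of the downstream correlation.

Heart rate counts *all* beats (sinus + PVC) per valid second: under the
blocked-compensatory-pause assumption each PVC substitutes exactly one
sinus beat, so the total beat rate equals the underlying sinus rate.

Noise handling: masked 30-s segments contribute no valid time; counts in a
partially-masked interval are scaled by its valid seconds, and intervals
whose valid fraction falls below a configurable threshold (default 0.5) are
marked invalid and excluded from regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beat_record import BeatRecord, valid_time_in_window

#: The interval durations used throughout, in seconds.
HOUR = 3600.0
TEN_MIN = 600.0
MINUTE = 60.0

DAY_S = 86400.0

#: Minimum fraction of un-masked time for an interval to enter regressions.
DEFAULT_VALIDITY_THRESHOLD = 0.5

#: A 24-h section needs at least this many valid intervals to be classified.
DEFAULT_MIN_VALID_INTERVALS = 10

#: A heart-rate bin is emitted only with strictly more than this many minutes.
HR_BIN_MIN_MINUTES = 10


@dataclass(frozen=True)
class IntervalSummary:
    """Metrics for one half-open window ``[start, start + duration_nominal)``."""

    start: float
    duration_nominal: float
    valid_seconds: float
    mean_hr: float
    pvc_count: int
    pvc_per_hour: float
    day_index: int
    valid: bool


@dataclass(frozen=True)
class AggregatedBin:
    """One integer-bpm heart-rate bin of aggregated 1-minute intervals."""

    hr_bin: int
    n_minutes: int
    pvc_per_hour: float


@dataclass(frozen=True)
class DaySection:
    """The interval summaries of one 24-hour section of a record."""

    day_index: int
    intervals: tuple[IntervalSummary, ...]
    partial: bool
    usable: bool


def segment_record(
    record: BeatRecord,
    duration: float,
    validity_threshold: float = DEFAULT_VALIDITY_THRESHOLD,
) -> list[IntervalSummary]:
    """Cut a record into consecutive fixed-duration intervals from t = 0.

    mean_hr is ``60 * n_beats / valid_seconds`` and pvc_per_hour is
    ``pvc_count * 3600 / valid_seconds``; both are 0 when no valid time or
    no beats remain.  An interval is `valid` when its valid fraction of the
    nominal duration reaches `validity_threshold` (a trailing partial
    interval is naturally penalised by its missing time).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    total = record.total_duration
    if total <= 0:
        return []
    n_intervals = max(1, int(math.ceil(total / duration - 1e-9)))

    idx = np.minimum((record.times / duration).astype(int), n_intervals - 1)
    beats_per = np.bincount(idx, minlength=n_intervals)
    pvcs_per = np.bincount(idx, weights=record.is_pvc, minlength=n_intervals)

    out: list[IntervalSummary] = []
    for k in range(n_intervals):
        start = k * duration
        end = min(start + duration, total)
        valid_s = valid_time_in_window(record, start, end)
        n_beats = int(beats_per[k])
        n_pvc = int(pvcs_per[k])
        mean_hr = 60.0 * n_beats / valid_s if valid_s > 0 else 0.0
        rate = n_pvc * 3600.0 / valid_s if valid_s > 0 else 0.0
        out.append(
            IntervalSummary(
                start=start,
                duration_nominal=duration,
                valid_seconds=valid_s,
                mean_hr=mean_hr,
                pvc_count=n_pvc,
                pvc_per_hour=rate,
                day_index=int(start // DAY_S),
                valid=valid_s >= validity_threshold * duration and n_beats > 0,
            )
        )
    return out


def intervals_to_frame(intervals: list[IntervalSummary]) -> pd.DataFrame:
    """Tidy DataFrame export (columns match the CSV interface)."""
    return pd.DataFrame(
        {
            "start_s": [iv.start for iv in intervals],
            "duration_s": [iv.duration_nominal for iv in intervals],
            "valid_s": [iv.valid_seconds for iv in intervals],
            "mean_hr": [iv.mean_hr for iv in intervals],
            "pvc_count": [iv.pvc_count for iv in intervals],
            "pvc_per_hour": [iv.pvc_per_hour for iv in intervals],
            "day_index": [iv.day_index for iv in intervals],
            "valid": [iv.valid for iv in intervals],
        }
    )


def sections_24h(
    record: BeatRecord,
    duration: float = MINUTE,
    validity_threshold: float = DEFAULT_VALIDITY_THRESHOLD,
    min_valid_intervals: int = DEFAULT_MIN_VALID_INTERVALS,
    include_partial: bool = False,
) -> list[DaySection]:
    """Group interval summaries into consecutive 24-h sections from t = 0.

    A trailing section shorter than 24 h is flagged `partial` and, by
    default, marked unusable for per-day classification.  Sections with
    fewer than `min_valid_intervals` valid intervals are unusable (too few
    degrees of freedom for the regression).
    """
    intervals = segment_record(record, duration, validity_threshold)
    n_days = int(math.ceil(record.total_duration / DAY_S - 1e-9))
    sections: list[DaySection] = []
    for day in range(n_days):
        ivs = tuple(iv for iv in intervals if iv.day_index == day)
        partial = (day + 1) * DAY_S > record.total_duration + 1e-9
        n_valid = sum(iv.valid for iv in ivs)
        usable = n_valid >= min_valid_intervals and (include_partial or not partial)
        sections.append(DaySection(day, ivs, partial, usable))
    return sections


def aggregate_by_hr(
    minutes: list[IntervalSummary],
    min_minutes: int = HR_BIN_MIN_MINUTES,
) -> list[AggregatedBin]:
    """Aggregate valid 1-minute intervals into integer-bpm heart-rate bins.

    Minutes are assigned by rounding mean_hr to the nearest integer (ties to
    even); a bin is emitted only when strictly more than `min_minutes`
    minutes fall in it, with pvc_per_hour = 60 x the mean per-minute PVC
    count — at most one data point per heart rate.
    """
    for iv in minutes:
        if iv.duration_nominal != MINUTE:
            raise ValueError(
                "aggregate_by_hr expects 1-minute interval summaries, got "
                f"duration {iv.duration_nominal} s"
            )
    usable = [iv for iv in minutes if iv.valid]
    if not usable:
        return []
    hr_bins = np.rint([iv.mean_hr for iv in usable]).astype(int)
    counts = np.array([iv.pvc_count for iv in usable], dtype=float)
    out: list[AggregatedBin] = []
    for hr in np.unique(hr_bins):
        sel = hr_bins == hr
        n = int(sel.sum())
        if n > min_minutes:
            out.append(AggregatedBin(int(hr), n, 60.0 * float(counts[sel].mean())))
    return out


def log_transform(
    points: np.ndarray | list[tuple[float, float]],
) -> tuple[np.ndarray, int]:
    """Map (hr, rate) points to (hr, log10 rate), dropping zero-rate points.

    A zero PVC count is undefined on the log scale, so such points are
    removed; the number dropped is returned because it changes the sample
    size (and hence the p-value) of the log-linear regression.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if np.any(pts[:, 1] < 0):
        raise ValueError("negative PVC rate")
    keep = pts[:, 1] > 0
    n_dropped = int((~keep).sum())
    out = pts[keep].copy()
    out[:, 1] = np.log10(out[:, 1])
    return out, n_dropped
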