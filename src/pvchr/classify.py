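"""Pearson correlation, OLS slope, Wald p-value, and the PVC-HR class label.

A record (or one 24-hour section of it) is classified by the linear
association between heart rate X and PVC rate Y:

* ``r = Cov(X, Y) / (sigma_X sigma_Y)``
* ``B = Cov(X, Y) / sigma_X^2`` (ordinary least squares slope)
* two-sided p-value from the Wald test with
  ``t = r sqrt(n - 2) / sqrt(1 - r^2)`` on ``n - 2`` degrees of freedom

and the label rule: POSITIVE when ``r > 0`` and ``p < .05``, NEGATIVE when
``r < 0`` and ``p < .05``, NEUTRAL when ``p >= .05`` (the boundary atom
``p = .05`` is assigned to NEUTRAL, the conservative reading of the rule).

Four methodologies are crossed with a linear or log-linear scale:
1-hour, 10-minute, and 1-minute intervals, and 1-minute intervals
aggregated by heart rate at 1-bpm spacing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .beat_record import BeatRecord
from .intervals import (
    DEFAULT_MIN_VALID_INTERVALS,
    DEFAULT_VALIDITY_THRESHOLD,
    HOUR,
    MINUTE,
    TEN_MIN,
    AggregatedBin,
    DaySection,
    IntervalSummary,
    aggregate_by_hr,
    log_transform,
    sections_24h,
    segment_record,
)

ALPHA = 0.05

#: day_index value marking a whole-record classification row.
WHOLE_RECORD = -1


class InsufficientDataError(ValueError):
    """Fewer than 3 paired points — r and the regression are undefined."""


class DegenerateInputError(ValueError):
    """One of the variables has zero variance."""


class Label(enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NEUTRAL = "neutral"
    UNUSABLE = "unusable"


class Scale(enum.Enum):
    LINEAR = "linear"
    LOG_LINEAR = "log"


@dataclass(frozen=True)
class Methodology:
    """One way of turning a record into (heart rate, PVC rate) points."""

    interval_duration: float = HOUR
    aggregated: bool = False
    scale: Scale = Scale.LINEAR

    def __post_init__(self) -> None:
        if self.interval_duration not in (HOUR, TEN_MIN, MINUTE):
            raise ValueError(
                "interval_duration must be 3600, 600 or 60 seconds"
            )
        if self.aggregated and self.interval_duration != MINUTE:
            raise ValueError("heart-rate aggregation requires 1-minute intervals")

    @property
    def name(self) -> str:
        base = {HOUR: "1 hr", TEN_MIN: "10 min", MINUTE: "1 min"}[
            self.interval_duration
        ]
        if self.aggregated:
            base += " agg."
        if self.scale is Scale.LOG_LINEAR:
            base += " (log)"
        return base


#: The four methodologies of the main analysis, on a linear scale.
STANDARD_METHODOLOGIES: tuple[Methodology, ...] = (
    Methodology(HOUR),
    Methodology(TEN_MIN),
    Methodology(MINUTE),
    Methodology(MINUTE, aggregated=True),
)

#: The same four on the log-linear scale.
LOG_METHODOLOGIES: tuple[Methodology, ...] = tuple(
    Methodology(m.interval_duration, m.aggregated, Scale.LOG_LINEAR)
    for m in STANDARD_METHODOLOGIES
)


@dataclass(frozen=True)
class ClassificationResult:
    """Correlation statistics and class label for one section/methodology."""

    r: float
    slope_B: float
    intercept: float
    p_value: float
    n_points: int
    label: Label
    methodology: Methodology
    day_index: int = WHOLE_RECORD
    n_zero_dropped: int = 0
    reason: str = ""


# -- elementary statistics ----------------------------------------------------

def _check_pairs(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.size < 3:
        raise InsufficientDataError(
            f"need at least 3 paired points, got {x.size}"
        )
    if np.ptp(x) == 0:
        raise DegenerateInputError("x (heart rate) has zero variance")
    if np.ptp(y) == 0:
        raise DegenerateInputError("y (PVC rate) has zero variance")
    return x, y


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient Cov(X,Y) / (sigma_X sigma_Y)."""
    x, y = _check_pairs(x, y)
    dx = x - x.mean()
    dy = y - y.mean()
    # sample (n-1) convention; the ratio is convention-independent
    cov = float(dx @ dy) / (x.size - 1)
    r = cov / (np.std(x, ddof=1) * np.std(y, ddof=1))
    return float(np.clip(r, -1.0, 1.0))


def ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Ordinary-least-squares slope Cov(X,Y)/Var(X) and intercept."""
    x, y = _check_pairs(x, y)
    dx = x - x.mean()
    dy = y - y.mean()
    slope = float(dx @ dy) / float(dx @ dx)
    return slope, float(y.mean() - slope * x.mean())


def wald_p(r: float, n: int) -> float:
    """Two-sided Wald-test p-value for Pearson r with a t reference.

    ``t = r sqrt(n-2) / sqrt(1-r^2)`` on ``n - 2`` degrees of freedom; the
    degenerate ``|r| = 1`` limit returns p = 0.
    """
    if n < 3:
        raise InsufficientDataError(f"need n >= 3, got {n}")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def assign_label(r: float, p: float) -> Label:
    if p < ALPHA:
        return Label.POSITIVE if r > 0 else Label.NEGATIVE
    return Label.NEUTRAL


# -- section and record classification ---------------------------------------

def _section_points(
    intervals: tuple[IntervalSummary, ...] | list[IntervalSummary],
    methodology: Methodology,
) -> np.ndarray:
    """(hr, pvc_per_hour) points for one section under one methodology."""
    valid = [iv for iv in intervals if iv.valid]
    if methodology.aggregated:
        bins: list[AggregatedBin] = aggregate_by_hr(valid)
        return np.array([(b.hr_bin, b.pvc_per_hour) for b in bins]).reshape(-1, 2)
    return np.array([(iv.mean_hr, iv.pvc_per_hour) for iv in valid]).reshape(-1, 2)


def classify_points(
    points: np.ndarray,
    methodology: Methodology,
    day_index: int = WHOLE_RECORD,
) -> ClassificationResult:
    """Classify a set of (hr, pvc_per_hour) points.

    Degenerate input (too few points, zero variance — e.g. a section with
    no PVCs at all) yields an explicit UNUSABLE result, never a silent
    NEUTRAL.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    n_dropped = 0
    if methodology.scale is Scale.LOG_LINEAR:
        points, n_dropped = log_transform(points)

    def unusable(reason: str) -> ClassificationResult:
        return ClassificationResult(
            r=np.nan,
            slope_B=np.nan,
            intercept=np.nan,
            p_value=np.nan,
            n_points=int(points.shape[0]),
            label=Label.UNUSABLE,
            methodology=methodology,
            day_index=day_index,
            n_zero_dropped=n_dropped,
            reason=reason,
        )

    try:
        x, y = _check_pairs(points[:, 0], points[:, 1])
    except (InsufficientDataError, DegenerateInputError) as exc:
        return unusable(str(exc))
    r = pearson_r(x, y)
    slope, intercept = ols_slope(x, y)
    p = wald_p(r, x.size)
    return ClassificationResult(
        r=r,
        slope_B=slope,
        intercept=intercept,
        p_value=p,
        n_points=int(x.size),
        label=assign_label(r, p),
        methodology=methodology,
        day_index=day_index,
        n_zero_dropped=n_dropped,
    )


def classify_section(
    section: DaySection,
    methodology: Methodology,
) -> ClassificationResult:
    """Classify one 24-h section (UNUSABLE when the section fails the
    minimum-data rule)."""
    if not section.usable:
        return ClassificationResult(
            r=np.nan,
            slope_B=np.nan,
            intercept=np.nan,
            p_value=np.nan,
            n_points=0,
            label=Label.UNUSABLE,
            methodology=methodology,
            day_index=section.day_index,
            reason="section fails the minimum-data rule",
        )
    pts = _section_points(section.intervals, methodology)
    return classify_points(pts, methodology, day_index=section.day_index)


def classify_record(
    record: BeatRecord,
    methodologies: tuple[Methodology, ...] = STANDARD_METHODOLOGIES,
    validity_threshold: float = DEFAULT_VALIDITY_THRESHOLD,
    min_valid_intervals: int = DEFAULT_MIN_VALID_INTERVALS,
) -> list[ClassificationResult]:
    """Classify every usable 24-h section and the whole record.

    Returns one :class:`ClassificationResult` per (methodology x usable
    day) plus one whole-record result per methodology (day_index = -1).
    The computation is deterministic.
    """
    results: list[ClassificationResult] = []
    for meth in methodologies:
        intervals = segment_record(record, meth.interval_duration, validity_threshold)
        sections = sections_24h(
            record,
            meth.interval_duration,
            validity_threshold,
            min_valid_intervals,
        )
        for section in sections:
            results.append(classify_section(section, meth))
        whole_pts = _section_points(intervals, meth)
        results.append(classify_points(whole_pts, meth, day_index=WHOLE_RECORD))
    return results


def results_to_frame(
    results: list[ClassificationResult],
    record_id: str | None = None,
) -> pd.DataFrame:
    """Tidy CSV-ready table: record_id, day_index, methodology, n, r, B, p, label."""
    df = pd.DataFrame(
        {
            "day_index": [res.day_index for res in results],
            "methodology": [res.methodology.name for res in results],
            "scale": [res.methodology.scale.value for res in results],
            "n_points": [res.n_points for res in results],
            "n_zero_dropped": [res.n_zero_dropped for res in results],
            "r": [res.r for res in results],
            "slope": [res.slope_B for res in results],
            "p": [res.p_value for res in results],
            "label": [res.label.value for res in results],
        }
    )
    if record_id is not None:
        df.insert(0, "record_id", record_id)
    return df


def classify_cohort(
    records: list[BeatRecord],
    methodologies: tuple[Methodology, ...] = STANDARD_METHODOLOGIES,
    **kwargs,
) -> pd.DataFrame:
    """Per-record classification tables concatenated across a cohort."""
    frames = [
        results_to_frame(classify_record(rec, methodologies, **kwargs), rec.record_id)
        for rec in records
    ]
    return pd.concat(frames, ignore_index=True)


def cohort_proportions(results: pd.DataFrame) -> pd.DataFrame:
    """Per-(methodology, day) class proportions across a cohort.

    Rows are (methodology, label in positive/neutral/negative), columns are
    day indices; each (methodology, day) triple of fractions sums to 1 over
    the usable records of that cell.  Whole-record rows (day_index = -1)
    are excluded.  Cells with no usable record are NaN.
    """
    daily = results[
        (results["day_index"] != WHOLE_RECORD)
        & (results["label"] != Label.UNUSABLE.value)
    ]
    classes = [Label.POSITIVE.value, Label.NEUTRAL.value, Label.NEGATIVE.value]
    rows = []
    for meth in daily["methodology"].unique():
        sub = daily[daily["methodology"] == meth]
        for cls in classes:
            row: dict = {"methodology": meth, "label": cls}
            for day in sorted(sub["day_index"].unique()):
                cell = sub[sub["day_index"] == day]
                row[day] = (cell["label"] == cls).mean() if len(cell) else np.nan
            rows.append(row)
    return pd.DataFrame(rows).set_index(["methodology", "label"])
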