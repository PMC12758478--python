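"""NIB rhythms: intervening-beat counts and per-minute stable-rhythm labels.

The NIB (number of intervening beats) of a pair of consecutive PVCs is the
count of sinus beats strictly between them: NIB 1 is bigeminy, NIB 2
trigeminy.  A minute exhibits a *stable rhythm* when at least two NIB
values are observed and all are equal — a single NIB value cannot evidence
repetition.  Under the blocked-compensatory-pause assumption a stable
NIB-k rhythm produces ``HR / (k + 1)`` PVCs per minute, an increasing
linear function of heart rate with slope ``1 / (k + 1)``; minutes are
compared against this prediction.

NIB pairs are confined to a single minute and never span noise-masked
gaps (missing beats make the intervening count undefined).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .beat_record import BeatRecord
from .intervals import DEFAULT_VALIDITY_THRESHOLD, MINUTE, IntervalSummary, segment_record


@dataclass(frozen=True)
class MinuteRhythm:
    """Rhythm label and NIB values for one 1-minute interval.

    `label` is one of ``no_pvc`` (zero PVCs), ``fixed_nib`` (>= 2 NIB
    values, all equal to `nib`), ``mixed`` (unequal NIB values), or
    ``insufficient`` (PVCs present but fewer than 2 NIB values).
    """

    minute_start: float
    nib_values: tuple[int, ...]
    pvc_count: int
    mean_hr: float
    label: str
    nib: int | None
    valid: bool
    valid_seconds: float = MINUTE


def nib_sequence(is_pvc: Sequence[bool] | np.ndarray) -> list[int]:
    """Counts of sinus beats strictly between consecutive PVCs.

    Empty or single-PVC input yields an empty list; a PVC couplet yields 0.
    """
    flags = np.asarray(is_pvc, dtype=bool)
    pvc_idx = np.nonzero(flags)[0]
    return [int(b - a - 1) for a, b in zip(pvc_idx[:-1], pvc_idx[1:])]


def _rhythm_label(pvc_count: int, nibs: list[int]) -> tuple[str, int | None]:
    if pvc_count == 0:
        return "no_pvc", None
    if len(nibs) < 2:
        return "insufficient", None
    if len(set(nibs)) == 1:
        return "fixed_nib", nibs[0]
    return "mixed", None


def label_minutes(
    record: BeatRecord,
    validity_threshold: float = DEFAULT_VALIDITY_THRESHOLD,
) -> list[MinuteRhythm]:
    """Assign a rhythm label to every 1-minute interval of a record.

    Within a minute, beats are split into contiguous runs at noise-mask
    boundaries; NIB values are computed per run and concatenated, so no
    PVC pair spans a masked gap.
    """
    summaries = segment_record(record, MINUTE, validity_threshold)
    out: list[MinuteRhythm] = []
    for iv in summaries:
        start, end = iv.start, min(iv.start + MINUTE, record.total_duration)
        # contiguous valid runs inside the minute (mask is 30-s grid aligned)
        cuts = [start]
        for a, b in record.noise.segments:
            if a < end and b > start:
                cuts.extend([max(a, start), min(b, end)])
        cuts.append(end)
        cuts = sorted(set(cuts))
        nibs: list[int] = []
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            if record.noise.overlap(lo, hi) > 0:
                continue  # masked run
            _, flags = record.slice_window(lo, hi)
            nibs.extend(nib_sequence(flags))
        label, k = _rhythm_label(iv.pvc_count, nibs)
        out.append(
            MinuteRhythm(
                minute_start=iv.start,
                nib_values=tuple(nibs),
                pvc_count=iv.pvc_count,
                mean_hr=iv.mean_hr,
                label=label,
                nib=k,
                valid=iv.valid,
                valid_seconds=iv.valid_seconds,
            )
        )
    return out


def predicted_rate(nib: int, hr: float) -> float:
    """PVCs per minute of a stable NIB rhythm: ``hr / (nib + 1)``."""
    if nib < 0:
        raise ValueError("nib must be >= 0")
    if hr <= 0:
        raise ValueError("hr must be positive")
    return hr / (nib + 1)


def rhythm_stratified_scatter(
    record: BeatRecord,
    validity_threshold: float = DEFAULT_VALIDITY_THRESHOLD,
) -> pd.DataFrame:
    """Per-minute table behind the mechanism-colored PVC-vs-HR scatter.

    One row per valid minute: mean heart rate, PVC count, rhythm label and,
    for stable fixed-NIB minutes, the analytically predicted per-minute PVC
    count ``HR / (NIB + 1)`` and the residual from it.
    """
    minutes = label_minutes(record, validity_threshold)
    rows = []
    for m in minutes:
        if not m.valid:
            continue
        pred = (
            predicted_rate(m.nib, m.mean_hr)
            if m.label == "fixed_nib" and m.mean_hr > 0
            else np.nan
        )
        # scale the raw count to a full nominal minute before comparing
        rate = m.pvc_count * MINUTE / m.valid_seconds if m.valid_seconds > 0 else 0.0
        rows.append(
            {
                "minute_start": m.minute_start,
                "mean_hr": m.mean_hr,
                "pvc_count": m.pvc_count,
                "pvc_per_min": rate,
                "label": m.label,
                "nib": m.nib if m.nib is not None else np.nan,
                "predicted_pvc_per_min": pred,
                "residual": rate - pred if not math.isnan(pred) else np.nan,
            }
        )
    return pd.DataFrame(rows)
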