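"""Day-to-day classification consistency: entropy, agreement, ternary sets.

A patient classified on each usable 24-hour section receives a list of
daily class labels (positive / negative / neutral).  Consistency of that
list is quantified by

* the normalized Shannon entropy
  ``H = -sum_c p(c) log2 p(c) / log2 3`` of the label proportions (0 means
  the same class every day; the 0 log 0 term is taken as 0),
* the probability that two 24-hour sections drawn at random *without
  replacement* receive the same class, and
* the ternary coordinates (fraction positive, fraction negative, fraction
  neutral), a point on the 2-simplex.

Days with an UNUSABLE classification are omitted from the label list —
the class set has exactly three members.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import WHOLE_RECORD, Label

_CLASSES = (Label.POSITIVE.value, Label.NEGATIVE.value, Label.NEUTRAL.value)


def _as_values(labels: Sequence) -> list[str]:
    vals = [l.value if isinstance(l, Label) else str(l) for l in labels]
    bad = [v for v in vals if v not in _CLASSES]
    if bad:
        raise ValueError(f"labels outside the class set {_CLASSES}: {bad}")
    return vals


def entropy_normalized(labels: Sequence, normalize: str = "log2_3") -> float:
    """Normalized Shannon entropy of a daily-label list, in [0, 1].

    ``normalize="log2_3"`` (default) divides by log2 3, the entropy of a
    uniform three-class distribution. ``normalize="max_attainable"``
    divides instead by the entropy of the most even integer partition of
    the day count into three classes (for 7 days: frequencies 2, 2, 3),
    so the observed maximum maps to 1.
    """
    vals = _as_values(labels)
    if not vals:
        raise ValueError("need at least one label")
    n = len(vals)
    counts = Counter(vals)
    if len(counts) == 1:
        return 0.0  # exactly consistent: entropy is identically zero
    h = -sum((c / n) * math.log2(c / n) for c in counts.values() if c > 0)
    if normalize == "log2_3":
        h_max = math.log2(3)
    elif normalize == "max_attainable":
        base, rem = divmod(n, 3)
        parts = [base + (1 if i < rem else 0) for i in range(3)]
        h_max = -sum((p / n) * math.log2(p / n) for p in parts if p > 0)
    else:
        raise ValueError(f"unknown normalization {normalize!r}")
    return h / h_max if h_max > 0 else 0.0


def pair_agreement(labels: Sequence) -> float:
    """Probability two distinct randomly drawn days share a class.

    Drawing without replacement: ``sum_c C(n_c, 2) / C(n, 2)``.
    """
    vals = _as_values(labels)
    n = len(vals)
    if n < 2:
        raise ValueError("pair agreement needs at least 2 labels")
    same = sum(math.comb(c, 2) for c in Counter(vals).values())
    return same / math.comb(n, 2)


def ternary_coordinates(labels: Sequence) -> tuple[float, float, float]:
    """(fraction positive, fraction negative, fraction neutral)."""
    vals = _as_values(labels)
    if not vals:
        raise ValueError("need at least one label")
    n = len(vals)
    c = Counter(vals)
    return (
        c[Label.POSITIVE.value] / n,
        c[Label.NEGATIVE.value] / n,
        c[Label.NEUTRAL.value] / n,
    )


@dataclass(frozen=True)
class ConsistencyProfile:
    """Per-record consistency summary for one methodology."""

    record_id: str
    methodology: str
    daily_labels: tuple[str, ...]
    entropy_normalized: float
    pair_agreement: float
    ternary: tuple[float, float, float]


def build_profiles(
    results: pd.DataFrame,
    normalize: str = "log2_3",
) -> list[ConsistencyProfile]:
    """Consistency profiles from a tidy cohort classification table.

    Uses the per-day rows (day_index >= 0), dropping UNUSABLE days; records
    with fewer than two usable days are skipped (no day-to-day consistency
    is defined for them).
    """
    daily = results[
        (results["day_index"] != WHOLE_RECORD)
        & (results["label"] != Label.UNUSABLE.value)
    ]
    profiles: list[ConsistencyProfile] = []
    for (rid, meth), grp in daily.groupby(["record_id", "methodology"], sort=True):
        labels = tuple(grp.sort_values("day_index")["label"])
        if len(labels) < 2:
            continue
        profiles.append(
            ConsistencyProfile(
                record_id=rid,
                methodology=meth,
                daily_labels=labels,
                entropy_normalized=entropy_normalized(labels, normalize),
                pair_agreement=pair_agreement(labels),
                ternary=ternary_coordinates(labels),
            )
        )
    return profiles


def profiles_to_frame(profiles: list[ConsistencyProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "record_id": [p.record_id for p in profiles],
            "methodology": [p.methodology for p in profiles],
            "n_days": [len(p.daily_labels) for p in profiles],
            "entropy": [p.entropy_normalized for p in profiles],
            "pair_agreement": [p.pair_agreement for p in profiles],
            "frac_positive": [p.ternary[0] for p in profiles],
            "frac_negative": [p.ternary[1] for p in profiles],
            "frac_neutral": [p.ternary[2] for p in profiles],
        }
    )


def cohort_pair_agreement(profiles: list[ConsistencyProfile]) -> float:
    """Expected fraction of patients whose two random sections agree.

    The mean of the per-record pair agreement probabilities — the cohort
    expectation of two randomly selected 24-hour sections receiving the
    same classification.
    """
    if not profiles:
        raise ValueError("empty cohort")
    return float(np.mean([p.pair_agreement for p in profiles]))


def zero_entropy_fraction(profiles: list[ConsistencyProfile]) -> float:
    """Fraction of records with exactly zero entropy (fully consistent).

    Exact comparison is safe: the entropy is computed as exactly 0.0
    whenever the label list contains a single class.
    """
    if not profiles:
        raise ValueError("empty cohort")
    return float(np.mean([p.entropy_normalized == 0.0 for p in profiles]))


def entropy_by_class(
    results: pd.DataFrame,
    normalize: str = "log2_3",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair every daily classification event with its record's entropy.

    Returns ``(events, summary)``: `events` has one row per (record, day,
    methodology) daily classification carrying the owning record's
    normalized entropy for that methodology; `summary` groups events by
    (methodology, label) with median and quartiles — the box-plot view in
    which consistently positive patients sit at low entropy.
    """
    profiles = build_profiles(results, normalize)
    ent = {(p.record_id, p.methodology): p.entropy_normalized for p in profiles}
    daily = results[
        (results["day_index"] != WHOLE_RECORD)
        & (results["label"] != Label.UNUSABLE.value)
    ].copy()
    key = list(zip(daily["record_id"], daily["methodology"]))
    daily["entropy"] = [ent.get(k, np.nan) for k in key]
    events = daily.dropna(subset=["entropy"])[
        ["record_id", "methodology", "day_index", "label", "entropy"]
    ].reset_index(drop=True)
    summary = (
        events.groupby(["methodology", "label"])["entropy"]
        .agg(
            n="size",
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
        )
        .reset_index()
    )
    return events, summary
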