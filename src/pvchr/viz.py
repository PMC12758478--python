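"""Figure families: PVC-HR scatter, entropy heatmap, ternary density, NIB scatter.

Every plotting function returns ``(figure, data)`` where `data` is the
exact table being drawn, so figures are testable (and re-plottable) without
image comparison.  Class colors follow the field's convention: positive
blue, negative red, neutral gray.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .beat_record import BeatRecord
from .classify import (
    STANDARD_METHODOLOGIES,
    ClassificationResult,
    Label,
    Methodology,
    _section_points,
    classify_points,
)
from .consistency import ConsistencyProfile, profiles_to_frame
from .intervals import log_transform, segment_record
from .nib import rhythm_stratified_scatter

CLASS_COLORS = {
    Label.POSITIVE.value: "#2166ac",  # blue
    Label.NEGATIVE.value: "#b2182b",  # red
    Label.NEUTRAL.value: "#777777",  # gray
    Label.UNUSABLE.value: "#dddddd",
}


def plot_pvc_hr(
    record: BeatRecord,
    methodologies: tuple[Methodology, ...] = STANDARD_METHODOLOGIES,
) -> tuple[plt.Figure, pd.DataFrame]:
    """Scatter of hourly-scaled PVC rate vs heart rate per methodology.

    One panel per methodology with the regression line and an inset of r,
    p and the slope B; the y-axis is always the expected number of PVCs in
    one hour so panels are comparable across interval durations.
    """
    fig, axes = plt.subplots(
        1, len(methodologies), figsize=(4 * len(methodologies), 3.5), squeeze=False
    )
    frames = []
    for ax, meth in zip(axes[0], methodologies):
        intervals = segment_record(record, meth.interval_duration)
        pts = _section_points(intervals, meth)
        res = classify_points(pts, meth)
        plot_pts = pts
        if meth.scale.value == "log":
            plot_pts, _ = log_transform(pts)
        color = CLASS_COLORS[res.label.value]
        if plot_pts.size:
            ax.scatter(plot_pts[:, 0], plot_pts[:, 1], s=8, alpha=0.5, color=color)
        if res.label is not Label.UNUSABLE and plot_pts.size:
            xs = np.linspace(plot_pts[:, 0].min(), plot_pts[:, 0].max(), 50)
            ax.plot(xs, res.intercept + res.slope_B * xs, color=color, lw=1.5)
            ax.text(
                0.03,
                0.95,
                f"r={res.r:.2f}\nP={res.p_value:.3g}\nB={res.slope_B:.2f}",
                transform=ax.transAxes,
                va="top",
                fontsize=8,
            )
        ax.set_title(meth.name)
        ax.set_xlabel("heart rate (bpm)")
        frames.append(
            pd.DataFrame(
                {
                    "methodology": meth.name,
                    "hr": plot_pts[:, 0] if plot_pts.size else [],
                    "pvc_per_hour": plot_pts[:, 1] if plot_pts.size else [],
                    "label": res.label.value,
                }
            )
        )
    axes[0][0].set_ylabel("expected PVCs in 1 hour")
    fig.suptitle(record.record_id)
    fig.tight_layout()
    return fig, pd.concat(frames, ignore_index=True)


def plot_entropy_heatmap(
    profiles: list[ConsistencyProfile],
) -> tuple[plt.Figure, pd.DataFrame]:
    """Record x methodology heatmap of normalized entropy (0 yellow, 1 black)."""
    df = profiles_to_frame(profiles)
    mat = df.pivot(index="record_id", columns="methodology", values="entropy")
    fig, ax = plt.subplots(figsize=(1.2 * max(mat.shape[1], 2), 0.25 * len(mat) + 1.5))
    im = ax.imshow(
        mat.to_numpy(), cmap="cividis_r", vmin=0, vmax=1, aspect="auto"
    )
    ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=30, ha="right")
    ax.set_yticks(range(len(mat)), mat.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="normalized entropy")
    fig.tight_layout()
    return fig, mat.reset_index()


def _ternary_xy(frac_pos: np.ndarray, frac_neg: np.ndarray, frac_neu: np.ndarray):
    """Project simplex coordinates to the plane (equilateral triangle)."""
    x = frac_neg + 0.5 * frac_neu
    y = (np.sqrt(3) / 2) * frac_neu
    return x, y


def plot_ternary_density(
    profiles: list[ConsistencyProfile],
) -> tuple[plt.Figure, pd.DataFrame]:
    """Density of per-record classification sets on the class simplex.

    Corners are all-positive (left), all-negative (right) and all-neutral
    (top); a record sits at the relative frequencies of its daily classes.
    """
    df = profiles_to_frame(profiles)
    methods = df["methodology"].unique()
    fig, axes = plt.subplots(
        1, len(methods), figsize=(4 * len(methods), 3.8), squeeze=False
    )
    for ax, meth in zip(axes[0], methods):
        sub = df[df["methodology"] == meth]
        x, y = _ternary_xy(
            sub["frac_positive"].to_numpy(),
            sub["frac_negative"].to_numpy(),
            sub["frac_neutral"].to_numpy(),
        )
        tri = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2], [0, 0]])
        ax.plot(tri[:, 0], tri[:, 1], color="k", lw=1)
        if len(x):
            ax.hexbin(x, y, gridsize=15, cmap="Reds", mincnt=1, extent=(0, 1, 0, 0.9))
        ax.text(-0.02, -0.05, "positive", ha="left", fontsize=8)
        ax.text(1.02, -0.05, "negative", ha="right", fontsize=8)
        ax.text(0.5, np.sqrt(3) / 2 + 0.03, "neutral", ha="center", fontsize=8)
        ax.set_title(meth)
        ax.set_aspect("equal")
        ax.axis("off")
    fig.tight_layout()
    return fig, df


def plot_nib_scatter(record: BeatRecord) -> tuple[plt.Figure, pd.DataFrame]:
    """Per-minute PVC count vs heart rate, colored by stable NIB rhythm.

    Minutes without a repeating rhythm are gray and transparent; stable
    NIB-k minutes are colored, with the analytical line HR/(k+1) overlaid.
    """
    table = rhythm_stratified_scatter(record)
    fig, ax = plt.subplots(figsize=(5, 4))
    if len(table):
        rest = table[table["label"] != "fixed_nib"]
        ax.scatter(
            rest["mean_hr"], rest["pvc_per_min"], s=8, color="gray", alpha=0.25
        )
        stable = table[table["label"] == "fixed_nib"]
        cmap = plt.get_cmap("tab10")
        for i, k in enumerate(sorted(stable["nib"].dropna().unique())):
            sel = stable[stable["nib"] == k]
            ax.scatter(
                sel["mean_hr"],
                sel["pvc_per_min"],
                s=10,
                color=cmap(i % 10),
                label=f"NIB={int(k)}",
            )
            hr_lo, hr_hi = sel["mean_hr"].min(), sel["mean_hr"].max()
            xs = np.linspace(hr_lo, hr_hi, 20)
            ax.plot(xs, xs / (k + 1), color=cmap(i % 10), lw=1, ls="--")
        if len(stable):
            ax.legend(fontsize=8)
    ax.set_xlabel("heart rate (bpm)")
    ax.set_ylabel("PVCs per minute")
    ax.set_title(record.record_id)
    fig.tight_layout()
    return fig, table
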