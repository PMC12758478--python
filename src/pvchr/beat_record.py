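"""Beat-annotation records: data model and I/O.

A Holter analysis starts from a time-ordered sequence of annotated beats
(sinus ``N`` or premature ventricular complex ``V``) plus a noise mask of
discarded 30-second segments.  Everything downstream — interval metrics,
correlation classification, NIB rhythm labelling — consumes the
:class:`BeatRecord` defined here.

Timestamps are seconds from record start (0-based, real-valued) and every
time window in the package is half-open ``[start, end)``, so boundary beats
are never double-counted.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("pvchr")

#: Noise is masked in fixed 30-second segments aligned to the record-start grid.
NOISE_SEGMENT_S = 30.0

#: Study-like recordings span 1-7 days; outside this we warn rather than fail.
MIN_STUDY_DURATION_S = 1 * 86400.0
MAX_STUDY_DURATION_S = 7 * 86400.0


class BeatLabel(enum.Enum):
    """Beat annotation: normal sinus beat or premature ventricular complex."""

    SINUS = "N"
    PVC = "V"


class FormatError(ValueError):
    """Raised when an input file cannot be parsed in the named format."""


class ValidationError(ValueError):
    """Raised when parsed data violates a record invariant."""


@dataclass(frozen=True)
class Beat:
    """A single annotated beat."""

    time: float
    label: BeatLabel


@dataclass(frozen=True)
class NoiseMask:
    """Excluded half-open 30-s windows, non-overlapping and grid-aligned.

    Segments must start on a multiple of 30 s from record start and have
    length exactly 30 s; free-form masks are rejected so that segmenting the
    record downstream can assume grid alignment.
    """

    segments: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        segs = tuple((float(a), float(b)) for a, b in self.segments)
        object.__setattr__(self, "segments", segs)
        prev_end = -np.inf
        for i, (start, end) in enumerate(segs):
            if not np.isclose(end - start, NOISE_SEGMENT_S):
                raise ValidationError(
                    f"noise segment {i} [{start}, {end}) is not exactly "
                    f"{NOISE_SEGMENT_S:.0f} s long"
                )
            if not np.isclose(start % NOISE_SEGMENT_S, 0.0) and not np.isclose(
                start % NOISE_SEGMENT_S, NOISE_SEGMENT_S
            ):
                raise ValidationError(
                    f"noise segment {i} start {start} is not aligned to the "
                    f"{NOISE_SEGMENT_S:.0f}-s grid"
                )
            if start < prev_end:
                raise ValidationError(
                    f"noise segments overlap or are unsorted at index {i}"
                )
            prev_end = end
        starts = np.array([s for s, _ in segs])
        ends = np.array([e for _, e in segs])
        object.__setattr__(self, "_starts", starts)
        object.__setattr__(self, "_ends", ends)
        # sorted edge array for O(log n) point-in-mask queries
        object.__setattr__(self, "_edges", np.column_stack([starts, ends]).ravel())

    @property
    def total_excluded(self) -> float:
        return sum(end - start for start, end in self.segments)

    def overlap(self, start: float, end: float) -> float:
        """Total overlap of the mask with the half-open window [start, end)."""
        if end < start:
            raise ValueError(f"inverted window [{start}, {end})")
        if not self.segments:
            return 0.0
        clipped = np.minimum(self._ends, end) - np.maximum(self._starts, start)
        return float(np.clip(clipped, 0.0, None).sum())

    def contains(self, times: np.ndarray) -> np.ndarray:
        """Boolean array: which of `times` fall inside an excluded segment."""
        times = np.asarray(times, dtype=float)
        if not self.segments:
            return np.zeros(times.shape, dtype=bool)
        # odd insertion index into [a0,b0,a1,b1,...] means inside a segment
        return np.searchsorted(self._edges, times, side="right") % 2 == 1


@dataclass
class BeatRecord:
    """A multi-day beat-annotation recording.

    Beats are stored as parallel arrays (`times` in seconds, boolean
    `is_pvc`) for vectorised downstream processing; :meth:`beats` iterates
    them as :class:`Beat` objects.
    """

    record_id: str
    times: np.ndarray
    is_pvc: np.ndarray
    noise: NoiseMask = field(default_factory=NoiseMask)
    total_duration: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.is_pvc = np.asarray(self.is_pvc, dtype=bool)
        if self.times.shape != self.is_pvc.shape:
            raise ValidationError("times and is_pvc must have equal length")
        if self.times.size and np.any(self.times < 0):
            raise ValidationError("beat times must be non-negative")
        if self.times.size:
            bad = np.nonzero(np.diff(self.times) <= 0)[0]
            if bad.size:
                raise ValidationError(
                    f"beat times not strictly increasing at index {bad[0] + 1}"
                )
        if self.total_duration <= 0.0:
            self.total_duration = float(self.times[-1] + 1.0) if self.times.size else 0.0
        if self.times.size and self.times[-1] >= self.total_duration:
            raise ValidationError("all beat times must be < total_duration")
        inside = self.noise.contains(self.times)
        if inside.any():
            raise ValidationError(
                f"{int(inside.sum())} beats fall inside noise-masked segments; "
                "drop them before constructing the record"
            )
        if self.total_duration and not (
            MIN_STUDY_DURATION_S <= self.total_duration <= MAX_STUDY_DURATION_S
        ):
            warnings.warn(
                f"record '{self.record_id}' duration "
                f"{self.total_duration / 86400:.2f} days is outside the "
                "study-like 1-7 day range",
                stacklevel=2,
            )

    # -- convenience ---------------------------------------------------------

    @property
    def n_beats(self) -> int:
        return int(self.times.size)

    @property
    def n_pvc(self) -> int:
        return int(self.is_pvc.sum())

    @property
    def pvc_burden(self) -> float:
        """Fraction of all beats that are PVCs."""
        return self.n_pvc / self.n_beats if self.n_beats else 0.0

    def beats(self) -> Iterator[Beat]:
        for t, v in zip(self.times, self.is_pvc):
            yield Beat(float(t), BeatLabel.PVC if v else BeatLabel.SINUS)

    def slice_window(self, start: float, end: float) -> tuple[np.ndarray, np.ndarray]:
        """Beat times and PVC flags in the half-open window [start, end)."""
        i = np.searchsorted(self.times, start, side="left")
        j = np.searchsorted(self.times, end, side="left")
        return self.times[i:j], self.is_pvc[i:j]


def drop_masked_beats(
    times: np.ndarray, is_pvc: np.ndarray, noise: NoiseMask
) -> tuple[np.ndarray, np.ndarray, int]:
    """Remove beats inside excluded segments; return arrays and drop count."""
    inside = noise.contains(times)
    n_dropped = int(inside.sum())
    return times[~inside], is_pvc[~inside], n_dropped


def valid_time_in_window(record: BeatRecord, start: float, end: float) -> float:
    """Seconds of un-masked time inside the half-open window [start, end).

    Returns the window length minus its total overlap with the record's
    excluded noise segments; the result lies in [0, end - start].
    """
    if end < start:
        raise ValueError(f"inverted window [{start}, {end})")
    return (end - start) - record.noise.overlap(start, end)


# -- I/O ----------------------------------------------------------------------

_LABEL_MAP = {"N": False, "V": True}


def _parse_rdann_time(token: str) -> float:
    """Parse an elapsed-time token: plain seconds or [[h:]m:]s.sss."""
    parts = token.split(":")
    try:
        seconds = float(parts[-1])
        for mult, p in zip((60.0, 3600.0), reversed(parts[:-1])):
            seconds += mult * float(p)
    except ValueError as exc:
        raise FormatError(f"unparseable time token {token!r}") from exc
    return seconds


def read_noise_mask(path: str | Path) -> NoiseMask:
    """Read a noise-mask sidecar CSV with columns start_s, end_s."""
    df = pd.read_csv(path)
    if not {"start_s", "end_s"}.issubset(df.columns):
        raise FormatError(f"{path}: noise mask needs columns start_s,end_s")
    return NoiseMask(tuple(zip(df["start_s"].astype(float), df["end_s"].astype(float))))


def write_noise_mask(mask: NoiseMask, path: str | Path) -> None:
    pd.DataFrame(mask.segments, columns=["start_s", "end_s"]).to_csv(path, index=False)


def read_beat_record(
    path: str | Path,
    format_name: str = "csv",
    *,
    mask_path: str | Path | None = None,
    record_id: str | None = None,
    total_duration: float | None = None,
) -> BeatRecord:
    """Read a beat-annotation file into a :class:`BeatRecord`.

    Parameters
    ----------
    path
        Input file. Two formats are supported: ``"csv"`` — two columns
        ``time_s,label`` with a header row and labels N/V; ``"wfdb-text"`` —
        the whitespace-delimited plain-text export of WFDB annotations
        (elapsed time, sample number, beat symbol, ...).
    mask_path
        Optional noise-mask sidecar (CSV of start_s,end_s). If omitted, a
        file named ``<path stem>.mask.csv`` next to the input is used when
        present.
    record_id
        Defaults to the file stem.
    total_duration
        Record length in seconds; defaults to the last beat time rounded up
        to the next 30-s grid line.

    Beats inside masked segments are dropped (with a logged count), as are
    beats carrying labels other than N/V (artifact codes etc.).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rid = record_id if record_id is not None else path.stem

    if format_name == "csv":
        try:
            df = pd.read_csv(path, dtype={"time_s": float, "label": str})
        except Exception as exc:  # pragma: no cover - pandas error variety
            raise FormatError(f"{path}: cannot parse as CSV ({exc})") from exc
        if not {"time_s", "label"}.issubset(df.columns):
            raise FormatError(f"{path}: expected header columns time_s,label")
        times = df["time_s"].to_numpy(dtype=float)
        labels = df["label"].astype(str).str.strip().to_numpy()
    elif format_name == "wfdb-text":
        times_l: list[float] = []
        labels_l: list[str] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                tokens = line.split()
                if not tokens or tokens[0].startswith("#"):
                    continue
                if len(tokens) < 3:
                    raise FormatError(
                        f"{path}:{lineno}: expected at least 3 whitespace-"
                        "separated columns (time, sample, symbol)"
                    )
                times_l.append(_parse_rdann_time(tokens[0]))
                labels_l.append(tokens[2])
        times = np.asarray(times_l, dtype=float)
        labels = np.asarray(labels_l, dtype=object)
    else:
        raise FormatError(f"unknown format {format_name!r}")

    if times.size:
        bad = np.nonzero(np.diff(times) <= 0)[0]
        if bad.size:
            # +1 to name the offending beat; +1 more in CSV for the header row
            row = int(bad[0]) + 1
            raise ValidationError(
                f"{path}: timestamps not strictly increasing at beat index {row}"
            )

    known = np.isin(labels, list(_LABEL_MAP))
    n_unknown = int((~known).sum())
    if n_unknown:
        logger.info("%s: dropped %d beats with non-N/V labels", rid, n_unknown)
    times = times[known]
    is_pvc = np.array([_LABEL_MAP[l] for l in labels[known]], dtype=bool)

    if mask_path is None:
        candidate = path.parent / (path.stem + ".mask.csv")
        mask_path = candidate if candidate.exists() else None
    mask = read_noise_mask(mask_path) if mask_path is not None else NoiseMask()

    times, is_pvc, n_dropped = drop_masked_beats(times, is_pvc, mask)
    if n_dropped:
        logger.info("%s: dropped %d beats inside noise segments", rid, n_dropped)

    if total_duration is None:
        if times.size:
            total_duration = (
                float(np.ceil((times[-1] + 1e-9) / NOISE_SEGMENT_S)) * NOISE_SEGMENT_S
            )
        else:
            total_duration = max(
                (end for _, end in mask.segments), default=NOISE_SEGMENT_S
            )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duration warning is for interactive use
        rec = BeatRecord(rid, times, is_pvc, mask, float(total_duration))
    return rec


def write_beat_record(
    record: BeatRecord,
    path: str | Path,
    *,
    mask_path: str | Path | None = None,
) -> None:
    """Write a record to the columnar CSV dialect (time_s,label).

    Times are written with millisecond precision, so a read/write round trip
    reproduces beat times to <= 1 ms and labels exactly.  A noise-mask
    sidecar is written to ``mask_path`` (default ``<stem>.mask.csv``) when
    the mask is non-empty.
    """
    path = Path(path)
    labels = np.where(record.is_pvc, "V", "N")
    df = pd.DataFrame({"time_s": record.times, "label": labels})
    df.to_csv(path, index=False, float_format="%.3f")
    if record.noise.segments:
        if mask_path is None:
            mask_path = path.parent / (path.stem + ".mask.csv")
        write_noise_mask(record.noise, mask_path)
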