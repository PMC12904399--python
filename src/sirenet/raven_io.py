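"""Raven selection-table I/O and labeled-segment manifests.

Ground truth for call detection arrives as Raven Pro "selection tables":
tab-separated files with one row per annotated sound, giving at least the
begin and end time of each call in seconds (and, optionally, its low/high
frequency bounds). This module parses and writes that dialect, turns a
table into fixed-width labeled segments (the unit of classification),
mines background-noise segments from the gaps between calls, and splits
segment manifests into train/validation sets.

Conventions
-----------
Segments are half-open intervals ``[t, t + window)``. A segment is
*positive* iff its intersection with some annotated call has positive
length — merely touching an endpoint does not count. Segments that
contain only part of a call ("partial positives") are positive.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CallAnnotation",
    "SelectionTable",
    "LabeledSegment",
    "DatasetManifest",
    "SelectionTableFormatError",
    "RAVEN_COLUMNS",
    "read_selection_table",
    "write_selection_table",
    "segment_and_label",
    "mine_negatives",
    "split_manifest",
    "read_manifest",
    "write_manifest",
]

#: Default Raven column-name dialect. Keys are our field names, values the
#: column headers as Raven exports them.
RAVEN_COLUMNS: Mapping[str, str] = {
    "begin_s": "Begin Time (s)",
    "end_s": "End Time (s)",
    "low_hz": "Low Freq (Hz)",
    "high_hz": "High Freq (Hz)",
}

_REQUIRED_FIELDS = ("begin_s", "end_s")


class SelectionTableFormatError(ValueError):
    """A selection table does not conform to the expected Raven dialect."""


@dataclass(frozen=True)
class CallAnnotation:
    """One annotated vocalization interval (the unit of ground truth)."""

    recording_id: str
    begin_s: float
    end_s: float
    low_hz: float | None = None
    high_hz: float | None = None
    label: str = "call"

    def __post_init__(self) -> None:
        if self.begin_s < 0:
            raise ValueError(f"begin_s must be >= 0, got {self.begin_s}")
        if self.end_s <= self.begin_s:
            raise ValueError(
                f"end_s must exceed begin_s, got [{self.begin_s}, {self.end_s}]"
            )
        if self.low_hz is not None and self.high_hz is not None:
            if not (self.high_hz > self.low_hz >= 0):
                raise ValueError(
                    f"need high_hz > low_hz >= 0, got ({self.low_hz}, {self.high_hz})"
                )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.begin_s


@dataclass(frozen=True)
class SelectionTable:
    """All annotations for one recording, sorted by begin time."""

    recording_id: str
    recording_duration_s: float
    annotations: tuple[CallAnnotation, ...] = ()

    def __post_init__(self) -> None:
        if self.recording_duration_s <= 0:
            raise ValueError("recording_duration_s must be positive")
        anns = tuple(sorted(self.annotations, key=lambda a: (a.begin_s, a.end_s)))
        clipped = []
        for a in anns:
            if a.begin_s >= self.recording_duration_s:
                warnings.warn(
                    f"{self.recording_id}: annotation at {a.begin_s:.4f}s starts "
                    "after the recording ends; dropped",
                    stacklevel=2,
                )
                continue
            if a.end_s > self.recording_duration_s:
                warnings.warn(
                    f"{self.recording_id}: annotation [{a.begin_s:.4f}, "
                    f"{a.end_s:.4f}]s exceeds recording duration "
                    f"{self.recording_duration_s:.4f}s; clipped",
                    stacklevel=2,
                )
                a = dataclasses.replace(a, end_s=self.recording_duration_s)
            clipped.append(a)
        object.__setattr__(self, "annotations", tuple(clipped))

    def __len__(self) -> int:
        return len(self.annotations)

    @property
    def total_call_seconds(self) -> float:
        return float(sum(a.duration_s for a in self.annotations))


@dataclass(frozen=True)
class LabeledSegment:
    """A fixed-width audio slice with a binary label.

    ``overlap_fraction`` is the largest fraction of the window covered by
    any single annotation; ``label == "positive"`` iff it is > 0.
    """

    recording_id: str
    start_s: float
    duration_s: float
    label: str
    overlap_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.label not in ("positive", "negative"):
            raise ValueError(f"label must be positive/negative, got {self.label!r}")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if (self.label == "positive") != (self.overlap_fraction > 0):
            raise ValueError("label must be positive iff overlap_fraction > 0")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass
class DatasetManifest:
    """Labeled segments with a per-row train/val/test split assignment."""

    rows: list[LabeledSegment]
    split: list[str]
    seed: int

    def __post_init__(self) -> None:
        if len(self.rows) != len(self.split):
            raise ValueError("rows and split must have equal length")
        bad = set(self.split) - {"train", "val", "test"}
        if bad:
            raise ValueError(f"unknown split labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.rows)

    def subset(self, split: str) -> list[LabeledSegment]:
        return [r for r, s in zip(self.rows, self.split) if s == split]

    def class_counts(self) -> dict[str, dict[str, int]]:
        """Per-split positive/negative counts (the split summary)."""
        out: dict[str, dict[str, int]] = {}
        for r, s in zip(self.rows, self.split):
            d = out.setdefault(s, {"positive": 0, "negative": 0})
            d[r.label] += 1
        return out


def read_selection_table(
    path: str | Path,
    recording_duration_s: float,
    *,
    recording_id: str | None = None,
    columns: Mapping[str, str] = RAVEN_COLUMNS,
) -> SelectionTable:
    """Parse a Raven-style tab-separated selection table.

    Parameters
    ----------
    path
        Tab-separated file with a header row. Must contain the begin/end
        time columns named in ``columns`` (Raven's ``"Begin Time (s)"`` /
        ``"End Time (s)"`` by default).
    recording_duration_s
        Duration of the recording the table annotates. Annotations that
        extend past it are clipped with a warning.
    recording_id
        Defaults to the file stem.
    columns
        Field-name -> header mapping for non-default dialects.

    Raises
    ------
    SelectionTableFormatError
        If a required column is missing (the message names it), a time
        cell is non-numeric (the message gives the row number), or a row
        has ``end <= begin``.
    """
    path = Path(path)
    rid = recording_id if recording_id is not None else path.stem
    df = pd.read_csv(path, sep="\t", dtype=str)
    for fld in _REQUIRED_FIELDS:
        if columns[fld] not in df.columns:
            raise SelectionTableFormatError(
                f"{path.name}: missing required column {columns[fld]!r}"
            )
    anns = []
    for i, row in df.iterrows():
        times = {}
        for fld in _REQUIRED_FIELDS:
            raw = row[columns[fld]]
            try:
                times[fld] = float(raw)
            except (TypeError, ValueError):
                raise SelectionTableFormatError(
                    f"{path.name}: non-numeric {columns[fld]!r} value {raw!r} "
                    f"in row {i + 1}"
                ) from None
        if times["end_s"] <= times["begin_s"]:
            raise SelectionTableFormatError(
                f"{path.name}: row {i + 1} has end <= begin "
                f"({times['begin_s']} >= {times['end_s']})"
            )
        freqs: dict[str, float | None] = {"low_hz": None, "high_hz": None}
        for fld in ("low_hz", "high_hz"):
            col = columns.get(fld)
            if col in df.columns and pd.notna(row[col]):
                try:
                    freqs[fld] = float(row[col])
                except ValueError:
                    freqs[fld] = None
        anns.append(CallAnnotation(rid, times["begin_s"], times["end_s"], **freqs))
    return SelectionTable(rid, recording_duration_s, tuple(anns))


def write_selection_table(table: SelectionTable, path: str | Path) -> Path:
    """Write a selection table in the Raven tab-separated dialect.

    Times are serialized with 4 decimal places, so a write/read
    round-trip preserves them to 1e-4 s. The standard Raven bookkeeping
    columns (Selection, View, Channel) are emitted for interoperability.
    """
    path = Path(path)
    rows = []
    for i, a in enumerate(table.annotations, start=1):
        rows.append(
            {
                "Selection": i,
                "View": "Spectrogram 1",
                "Channel": 1,
                RAVEN_COLUMNS["begin_s"]: f"{a.begin_s:.4f}",
                RAVEN_COLUMNS["end_s"]: f"{a.end_s:.4f}",
                RAVEN_COLUMNS["low_hz"]: "" if a.low_hz is None else f"{a.low_hz:.1f}",
                RAVEN_COLUMNS["high_hz"]: ""
                if a.high_hz is None
                else f"{a.high_hz:.1f}",
            }
        )
    cols = [
        "Selection",
        "View",
        "Channel",
        RAVEN_COLUMNS["begin_s"],
        RAVEN_COLUMNS["end_s"],
        RAVEN_COLUMNS["low_hz"],
        RAVEN_COLUMNS["high_hz"],
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    return path


#: overlaps below this (seconds) are float artifacts of the tiling
#: arithmetic, not real intersections; far below one sample at 96 kHz
_EPS_S = 1e-9


def _overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    length = min(a1, b1) - max(a0, b0)
    return length if length > _EPS_S else 0.0


def segment_and_label(
    table: SelectionTable,
    window_s: float = 0.2,
    stride_s: float = 0.2,
) -> list[LabeledSegment]:
    """Tile a recording into fixed windows and label each by call overlap.

    Windows ``[k*stride, k*stride + window)`` tile ``[0,
    recording_duration_s)``; the trailing remainder shorter than
    ``window_s`` is dropped. A window is positive iff its intersection
    with some annotation has positive length (touching an endpoint does
    not count); ``overlap_fraction`` is the best such intersection
    divided by ``window_s``.
    """
    if window_s <= 0 or stride_s <= 0:
        raise ValueError("window_s and stride_s must be positive")
    dur = table.recording_duration_s
    if window_s > dur:
        warnings.warn(
            f"{table.recording_id}: window {window_s}s exceeds recording "
            f"duration {dur}s; no segments produced",
            stacklevel=2,
        )
        return []
    # epsilon guards against float artifacts like 1.8/0.2 = 8.999999999999998
    n = int(np.floor((dur - window_s) / stride_s + 1e-9)) + 1
    segments = []
    for k in range(n):
        t0 = k * stride_s
        t1 = t0 + window_s
        best = 0.0
        for a in table.annotations:
            if a.begin_s >= t1:
                break
            best = max(best, _overlap(t0, t1, a.begin_s, a.end_s))
        frac = min(1.0, best / window_s)
        segments.append(
            LabeledSegment(
                table.recording_id,
                start_s=t0,
                duration_s=window_s,
                label="positive" if frac > 0 else "negative",
                overlap_fraction=frac,
            )
        )
    return segments


def mine_negatives(
    table: SelectionTable,
    window_s: float = 0.2,
    guard_s: float = 0.0,
) -> list[LabeledSegment]:
    """Extract background-noise segments from the gaps between calls.

    Each inter-call gap (including the stretch before the first call and
    after the last), shrunk by ``guard_s`` on both sides, is tiled from
    its start at stride ``window_s``; only windows fully inside the gap
    are kept. All returned segments are negative and, by construction,
    never overlap any annotation.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if guard_s < 0:
        raise ValueError("guard_s must be >= 0")
    edges = [0.0]
    for a in table.annotations:
        edges.extend((a.begin_s, a.end_s))
    edges.append(table.recording_duration_s)
    out = []
    for g0, g1 in zip(edges[0::2], edges[1::2]):
        lo, hi = g0 + guard_s, g1 - guard_s
        n = int(np.floor((hi - lo) / window_s + 1e-9)) if hi > lo else 0
        for k in range(n):
            out.append(
                LabeledSegment(
                    table.recording_id,
                    start_s=lo + k * window_s,
                    duration_s=window_s,
                    label="negative",
                )
            )
    return out


def split_manifest(
    rows: Sequence[LabeledSegment],
    train_fraction: float,
    seed: int,
) -> DatasetManifest:
    """Assign segments to train/val uniformly at random (seeded).

    Exactly ``round(n * train_fraction)`` rows go to train; assignment is
    deterministic in ``(rows, train_fraction, seed)``.
    """
    if not rows:
        raise ValueError("rows must be non-empty")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    n = len(rows)
    n_train = int(round(n * train_fraction))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    split = ["val"] * n
    for i in order[:n_train]:
        split[i] = "train"
    return DatasetManifest(rows=list(rows), split=split, seed=seed)


_MANIFEST_COLS = [
    "recording_id",
    "start_s",
    "duration_s",
    "label",
    "overlap_fraction",
    "split",
]


def write_manifest(manifest: DatasetManifest, path: str | Path) -> Path:
    """Serialize a manifest as CSV (one row per labeled segment)."""
    path = Path(path)
    recs = [
        {
            "recording_id": r.recording_id,
            "start_s": f"{r.start_s:.4f}",
            "duration_s": f"{r.duration_s:.4f}",
            "label": r.label,
            "overlap_fraction": f"{r.overlap_fraction:.6f}",
            "split": s,
        }
        for r, s in zip(manifest.rows, manifest.split)
    ]
    pd.DataFrame(recs, columns=_MANIFEST_COLS).to_csv(path, index=False)
    return path


def read_manifest(path: str | Path, seed: int = 0) -> DatasetManifest:
    """Read a manifest CSV written by :func:`write_manifest`."""
    df = pd.read_csv(path)
    missing = set(_MANIFEST_COLS) - set(df.columns)
    if missing:
        raise SelectionTableFormatError(f"manifest missing columns: {sorted(missing)}")
    rows = [
        LabeledSegment(
            str(r.recording_id),
            float(r.start_s),
            float(r.duration_s),
            str(r.label),
            float(r.overlap_fraction),
        )
        for r in df.itertuples()
    ]
    return DatasetManifest(rows=rows, split=[str(s) for s in df["split"]], seed=seed)
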