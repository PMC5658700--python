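"""Half-open genomic interval arithmetic.

Every coordinate in this package is 0-based, half-open (BED convention):
an interval ``[start, end)`` covers bases ``start .. end-1``.  Two
intervals overlap iff ``a.start < b.end and b.start < a.end``; an
interval that abuts another (``a.end == b.start``) does not overlap it.

The functions in this module operate on per-chromosome numpy arrays of
starts and ends.  Callers are responsible for splitting interval sets by
chromosome (see :func:`by_chrom`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "by_chrom",
    "merge_intervals",
    "union_length",
    "covered_fraction",
    "longest_overlapping_length",
    "windows_overlap",
    "count_points",
]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval with an optional strand.

    Raises ``ValueError`` unless ``start < end`` and ``chrom`` is
    non-empty.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end})"
            )
        if self.start < 0:
            raise ValueError("start must be >= 0")
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        """True iff ``other`` lies entirely within this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def by_chrom(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Split a BED-like frame (chrom/start/end) into per-chromosome
    sorted (starts, ends) arrays."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        order = np.argsort(sub["start"].to_numpy(), kind="stable")
        out[str(chrom)] = (
            sub["start"].to_numpy()[order].astype(np.int64),
            sub["end"].to_numpy()[order].astype(np.int64),
        )
    return out


def merge_intervals(
    starts: np.ndarray, ends: np.ndarray, max_gap: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Transitively merge intervals whose gap is <= ``max_gap``.

    The gap between ``[a, b)`` and ``[c, d)`` with ``c >= b`` is
    ``c - b``; abutting intervals have gap 0.  With the default
    ``max_gap=0`` this computes the plain interval union.  Output is
    sorted and pairwise separated by gaps > ``max_gap``.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts.copy(), ends.copy()
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s = [starts[0]]
    out_e = [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - out_e[-1] <= max_gap:
            if e > out_e[-1]:
                out_e[-1] = e
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def union_length(
    starts: np.ndarray,
    ends: np.ndarray,
    clip_start: int | None = None,
    clip_end: int | None = None,
) -> int:
    """Total number of bases covered by the union of the intervals,
    optionally clipped to ``[clip_start, clip_end)``."""
    ms, me = merge_intervals(starts, ends, max_gap=0)
    if clip_start is not None:
        ms = np.maximum(ms, clip_start)
    if clip_end is not None:
        me = np.minimum(me, clip_end)
    return int(np.maximum(me - ms, 0).sum())


def covered_fraction(
    window: GenomicInterval, starts: np.ndarray, ends: np.ndarray
) -> float:
    """Fraction of ``window`` covered by the union of the intervals."""
    cov = union_length(starts, ends, window.start, window.end)
    return cov / window.length


def longest_overlapping_length(
    window: GenomicInterval, starts: np.ndarray, ends: np.ndarray
) -> int:
    """Length of the longest interval that overlaps ``window``
    (the full interval length, not the intersection); 0 if none."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    hit = (starts < window.end) & (ends > window.start)
    if not hit.any():
        return 0
    return int((ends[hit] - starts[hit]).max())


def windows_overlap(
    win_starts: np.ndarray,
    win_ends: np.ndarray,
    region_starts: np.ndarray,
    region_ends: np.ndarray,
) -> np.ndarray:
    """Boolean array: does each window intersect >= 1 region?

    Regions are merged first, so the test is a binary search on the
    union rather than a quadratic scan.
    """
    win_starts = np.asarray(win_starts, dtype=np.int64)
    win_ends = np.asarray(win_ends, dtype=np.int64)
    ms, me = merge_intervals(region_starts, region_ends, max_gap=0)
    if ms.size == 0:
        return np.zeros(win_starts.shape, dtype=bool)
    # candidate: last merged interval starting before the window end
    idx = np.searchsorted(ms, win_ends, side="left") - 1
    ok = idx >= 0
    hit = np.zeros(win_starts.shape, dtype=bool)
    hit[ok] = me[idx[ok]] > win_starts[ok]
    return hit


def count_points(points: np.ndarray, start: int, end: int) -> int:
    """Number of (sorted) point positions in ``[start, end)``."""
    points = np.asarray(points)
    return int(
        np.searchsorted(points, end, side="left")
        - np.searchsorted(points, start, side="left")
    )
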