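"""Genomic interval containers and the overlap engine.

Coordinate conventions used throughout the package:

* Intervals (enhancers, genes, DHS peaks, motif instances, masks) are
  BED-style: 0-based, half-open ``[start, end)``.
* Variant positions in tables are 1-based (VCF-like).  A SNP at 1-based
  position ``pos`` overlaps interval ``[start, end)`` iff
  ``start <= pos - 1 < end``.

A SNP "overlaps" an annotation iff its single base lies inside an interval;
no padding is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from intervaltree import IntervalTree


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    strand: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains_point(self, pos0: int) -> bool:
        """Membership of a 0-based position."""
        return self.start <= pos0 < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class AnnotationSet:
    """A named collection of genomic intervals, indexed for overlap queries.

    Intervals are kept sorted per chromosome.  Point queries take 1-based
    SNP positions and convert internally; interval queries use 0-based
    half-open coordinates.
    """

    def __init__(self, label: str, intervals: Iterable[GenomicInterval] = ()):
        self.label = label
        self._by_chrom: dict[str, list[GenomicInterval]] = {}
        self._trees: dict[str, IntervalTree] = {}
        self._starts: dict[str, np.ndarray] = {}
        self._cummax_end: dict[str, np.ndarray] = {}
        for iv in intervals:
            self._by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in self._by_chrom.items():
            ivs.sort(key=lambda iv: (iv.start, iv.end))
            self._trees[chrom] = IntervalTree.from_tuples(
                (iv.start, iv.end, iv) for iv in ivs
            )
            starts = np.array([iv.start for iv in ivs], dtype=np.int64)
            ends = np.array([iv.end for iv in ivs], dtype=np.int64)
            self._starts[chrom] = starts
            # running max of ends supports O(log n) stabbing membership even
            # when intervals overlap each other
            self._cummax_end[chrom] = np.maximum.accumulate(ends)

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in sorted(self._by_chrom):
            yield from self._by_chrom[chrom]

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def intervals(self, chrom: str | None = None) -> list[GenomicInterval]:
        if chrom is not None:
            return list(self._by_chrom.get(chrom, []))
        return list(self)

    # -- queries ---------------------------------------------------------

    def query_point(self, chrom: str, pos: int) -> list[GenomicInterval]:
        """All intervals covering 1-based position ``pos``."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.at(pos - 1)]
        hits.sort(key=lambda iv: (iv.start, iv.end))
        return hits

    def query_interval(
        self, chrom: str, start: int, end: int
    ) -> list[GenomicInterval]:
        """All intervals with >= 1 bp intersection with ``[start, end)``."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(start, end)]
        hits.sort(key=lambda iv: (iv.start, iv.end))
        return hits

    def contains_points(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized membership for an array of 1-based positions.

        Returns a boolean array: does any interval cover each position?
        """
        positions = np.asarray(positions, dtype=np.int64)
        starts = self._starts.get(chrom)
        if starts is None:
            return np.zeros(positions.shape, dtype=bool)
        pos0 = positions - 1
        idx = np.searchsorted(starts, pos0, side="right")
        out = np.zeros(positions.shape, dtype=bool)
        nz = idx > 0
        out[nz] = self._cummax_end[chrom][idx[nz] - 1] > pos0[nz]
        return out

    def overlaps_interval(self, iv: GenomicInterval) -> bool:
        tree = self._trees.get(iv.chrom)
        return bool(tree is not None and tree.overlap(iv.start, iv.end))


def overlap_query(
    annotation: AnnotationSet, chrom: str, pos: int
) -> list[GenomicInterval]:
    """Intervals of ``annotation`` covering the 1-based SNP position."""
    return annotation.query_point(chrom, pos)


class SignalTrack:
    """A sparse step function over the genome with bedGraph semantics.

    Per chromosome, non-overlapping segments ``(start, end, value)``;
    positions absent from every segment have value 0.
    """

    def __init__(
        self,
        segments: Iterable[tuple[str, int, int, float]] = (),
        name: str = "signal",
    ):
        self.name = name
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in segments:
            if end <= start:
                raise ValueError(f"segment end <= start: {chrom}:{start}-{end}")
            if not np.isfinite(value):
                raise ValueError(f"non-finite signal value at {chrom}:{start}")
            by_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        for chrom, segs in by_chrom.items():
            segs.sort()
            s = np.array([x[0] for x in segs], dtype=np.int64)
            e = np.array([x[1] for x in segs], dtype=np.int64)
            v = np.array([x[2] for x in segs], dtype=float)
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"overlapping segments on {chrom}")
            self._starts[chrom], self._ends[chrom], self._values[chrom] = s, e, v

    def segments(self, chrom: str) -> Iterator[tuple[int, int, float]]:
        s = self._starts.get(chrom)
        if s is None:
            return
        for i in range(len(s)):
            yield int(s[i]), int(self._ends[chrom][i]), float(self._values[chrom][i])

    @property
    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Mean per-base value over ``[start, end)``; absent bases count 0."""
        if end <= start:
            raise ValueError("zero-length interval")
        s = self._starts.get(chrom)
        if s is None:
            return 0.0
        e, v = self._ends[chrom], self._values[chrom]
        lo = np.maximum(s, start)
        hi = np.minimum(e, end)
        ov = np.clip(hi - lo, 0, None)
        return float(np.dot(ov, v) / (end - start))

    def values_per_base(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-base values over ``[start, end)`` (absent bases 0)."""
        if end <= start:
            raise ValueError("zero-length interval")
        out = np.zeros(end - start, dtype=float)
        s = self._starts.get(chrom)
        if s is None:
            return out
        e, v = self._ends[chrom], self._values[chrom]
        for i in range(len(s)):
            lo, hi = max(int(s[i]), start), min(int(e[i]), end)
            if hi > lo:
                out[lo - start : hi - start] = v[i]
        return out


def merge_adjacent(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or book-ended intervals (per chromosome)."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out
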