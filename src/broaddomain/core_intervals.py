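"""Peak data model and interval algebra shared by all pipeline stages.

All coordinates are 0-based half-open (BED convention).  A :class:`Peak` is a
single called interval with optional cell-type / cohort provenance; a
:class:`PeakSet` is a sorted, duplicate-free collection of peaks, the unit on
which every breadth, specificity and overlap statistic downstream operates.

Overlap is defined the BEDTools way: two half-open intervals on the same
chromosome overlap iff ``min(end_a, end_b) - max(start_a, start_b) >= min_bp``
with ``min_bp = 1`` by default, so intervals that merely abut do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "Peak",
    "PeakSet",
    "peak_length",
    "overlaps",
    "intersect_flags",
    "intersect_count",
    "nearest_distance",
]


@dataclass(frozen=True, order=True)
class Peak:
    """A genomic interval (0-based half-open) with provenance labels."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: float = 0.0
    cell_type: Optional[str] = None
    cohort: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("peak chromosome name must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (start >= end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Integer midpoint, floor((start + end) / 2)."""
        return (self.start + self.end) // 2

    def with_labels(self, cell_type=None, cohort=None) -> "Peak":
        return replace(
            self,
            cell_type=self.cell_type if cell_type is None else cell_type,
            cohort=self.cohort if cohort is None else cohort,
        )


class PeakSet:
    """Sorted, exact-duplicate-free collection of :class:`Peak`.

    Sorting key is (chrom, start, end); exact duplicates (all coordinate
    fields equal) are collapsed on construction.
    """

    __slots__ = ("peaks", "provenance", "__dict__")

    def __init__(self, peaks: Iterable[Peak] = (), provenance: str = ""):
        seen = set()
        unique = []
        for p in sorted(peaks, key=lambda q: (q.chrom, q.start, q.end)):
            key = (p.chrom, p.start, p.end)
            if key not in seen:
                seen.add(key)
                unique.append(p)
        self.peaks: tuple[Peak, ...] = tuple(unique)
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i):
        return self.peaks[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, PeakSet) and self.peaks == other.peaks

    def __repr__(self) -> str:
        return f"PeakSet(n={len(self)}, provenance={self.provenance!r})"

    @cached_property
    def lengths(self) -> np.ndarray:
        return np.array([p.length for p in self.peaks], dtype=np.int64)

    @cached_property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(p.chrom for p in self.peaks))

    @cached_property
    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """chrom -> (starts, ends) as sorted int64 arrays."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        i = 0
        n = len(self.peaks)
        while i < n:
            chrom = self.peaks[i].chrom
            j = i
            while j < n and self.peaks[j].chrom == chrom:
                j += 1
            out[chrom] = (
                np.array([p.start for p in self.peaks[i:j]], dtype=np.int64),
                np.array([p.end for p in self.peaks[i:j]], dtype=np.int64),
            )
            i = j
        return out

    @cached_property
    def merged_by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Union of intervals per chromosome, as disjoint sorted (starts, ends)."""
        out = {}
        for chrom, (starts, ends) in self.by_chrom.items():
            m_starts, m_ends = [], []
            cur_s, cur_e = int(starts[0]), int(ends[0])
            for s, e in zip(starts[1:], ends[1:]):
                if s <= cur_e:  # touching intervals merge: union view only
                    cur_e = max(cur_e, int(e))
                else:
                    m_starts.append(cur_s)
                    m_ends.append(cur_e)
                    cur_s, cur_e = int(s), int(e)
            m_starts.append(cur_s)
            m_ends.append(cur_e)
            out[chrom] = (
                np.array(m_starts, dtype=np.int64),
                np.array(m_ends, dtype=np.int64),
            )
        return out

    def subset(self, mask: Sequence[bool], provenance: Optional[str] = None) -> "PeakSet":
        picked = [p for p, keep in zip(self.peaks, mask) if keep]
        return PeakSet(picked, provenance if provenance is not None else self.provenance)


def peak_length(peak: Peak) -> int:
    """Breadth of a peak in base pairs (end - start)."""
    return peak.end - peak.start


def overlaps(a: Peak, b: Peak, min_bp: int = 1) -> bool:
    """True iff a and b share >= min_bp bases on the same chromosome."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    if a.chrom != b.chrom:
        return False
    return min(a.end, b.end) - max(a.start, b.start) >= min_bp


def _flags_merged(
    q_starts: np.ndarray, q_ends: np.ndarray, m_starts: np.ndarray, m_ends: np.ndarray
) -> np.ndarray:
    """Vectorized: does each query interval hit the disjoint sorted union?"""
    idx = np.searchsorted(m_starts, q_starts, side="right") - 1
    hit = np.zeros(len(q_starts), dtype=bool)
    valid = idx >= 0
    hit[valid] = m_ends[idx[valid]] > q_starts[valid]
    nxt = idx + 1
    has_next = nxt < len(m_starts)
    hit[has_next] |= m_starts[nxt[has_next]] < q_ends[has_next]
    return hit


def intersect_flags(query: PeakSet, reference: PeakSet, min_bp: int = 1) -> np.ndarray:
    """Boolean array over query.peaks: overlapped by >= 1 reference peak?"""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    flags = np.zeros(len(query), dtype=bool)
    if len(query) == 0 or len(reference) == 0:
        return flags
    offset = 0
    if min_bp == 1:
        merged = reference.merged_by_chrom
        for chrom, (q_starts, q_ends) in query.by_chrom.items():
            if chrom in merged:
                m_starts, m_ends = merged[chrom]
                flags[offset : offset + len(q_starts)] = _flags_merged(
                    q_starts, q_ends, m_starts, m_ends
                )
            offset += len(q_starts)
        return flags
    # general minimum-overlap path via interval trees
    trees: dict[str, IntervalTree] = {}
    for chrom, (r_starts, r_ends) in reference.by_chrom.items():
        trees[chrom] = IntervalTree.from_tuples(zip(r_starts.tolist(), r_ends.tolist()))
    for chrom, (q_starts, q_ends) in query.by_chrom.items():
        tree = trees.get(chrom)
        if tree is not None:
            for k, (s, e) in enumerate(zip(q_starts.tolist(), q_ends.tolist())):
                for iv in tree.overlap(s, e):
                    if min(e, iv.end) - max(s, iv.begin) >= min_bp:
                        flags[offset + k] = True
                        break
        offset += len(q_starts)
    return flags


def intersect_count(query: PeakSet, reference: PeakSet, min_bp: int = 1) -> int:
    """Number of query peaks overlapping >= 1 reference peak by >= min_bp.

    Each query peak is counted at most once, matching peak-level overlap
    reporting (e.g. the cross-cohort reproducible-peak count).
    """
    return int(intersect_flags(query, reference, min_bp).sum())


def nearest_distance(
    peak: Peak,
    anchors: np.ndarray,
    strands: Optional[Sequence[str]] = None,
) -> Optional[tuple[int, int]]:
    """Signed distance from the peak midpoint to the nearest anchor position.

    ``anchors`` must be sorted ascending positions on the peak's chromosome.
    Returns (signed_distance, anchor_index), or None when no anchor exists.
    The sign follows gene orientation when ``strands`` is given: negative
    means the midpoint lies 5' of the anchor (upstream), so on '+' strand the
    distance is midpoint - anchor and on '-' strand it is anchor - midpoint.
    Ties in absolute distance resolve to the lower index.
    """
    anchors = np.asarray(anchors, dtype=np.int64)
    if anchors.size == 0:
        return None
    mid = peak.midpoint
    i = int(np.searchsorted(anchors, mid))
    best_idx = None
    best_abs = None
    for j in (i - 1, i):
        if 0 <= j < anchors.size:
            d = abs(int(anchors[j]) - mid)
            if best_abs is None or d < best_abs:
                best_abs = d
                best_idx = j
    assert best_idx is not None
    anchor = int(anchors[best_idx])
    strand = "+" if strands is None else strands[best_idx]
    signed = (mid - anchor) if strand != "-" else (anchor - mid)
    return signed, best_idx
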