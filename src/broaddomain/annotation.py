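"""Peak-to-gene annotation: feature categories and TSS-window statistics.

Every peak is assigned exactly one category against its nearest gene (by
absolute midpoint-to-TSS distance, ties broken by lexicographic gene id),
with a fixed priority:

    promoter-TSS > TTS > 5'UTR > exon > intron > 3'UTR > intergenic

"promoter-TSS" means the peak midpoint lies within +/- ``promoter_window``
(default 4 kb) of the TSS; "TTS" within +/- ``tts_window`` (default 1 kb) of
the transcription end.  Without CDS coordinates the UTR categories cannot be
resolved and are folded into "exon" (the gene-model table here carries exon
blocks only); this mirrors how reduced annotation tables degrade gracefully.

Distances are signed in gene orientation: negative = midpoint upstream (5')
of the TSS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core_intervals import Peak, PeakSet

__all__ = [
    "GeneModel",
    "FeatureCall",
    "TSSIndex",
    "classify_peak",
    "classify_peaks",
    "tss_window_fraction",
]

CATEGORIES = ("promoter-TSS", "TTS", "5'UTR", "exon", "intron", "3'UTR", "intergenic")


@dataclass(frozen=True)
class GeneModel:
    """Reduced per-gene model: strand, TSS, transcription end, exon blocks."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    tss: int
    tes: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        lo, hi = min(self.tss, self.tes), max(self.tss, self.tes)
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty exon block {s}-{e}")
            if s < lo or e > hi:
                raise ValueError(f"{self.gene_id}: exon {s}-{e} outside gene span")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exon blocks overlap or unsorted")
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return min(self.tss, self.tes), max(self.tss, self.tes)


@dataclass(frozen=True)
class FeatureCall:
    """One peak's category, nearest gene and signed TSS distance."""

    peak: Peak
    category: str
    gene_id: Optional[str]
    tss_distance: Optional[int]  # None = no gene on the chromosome


class TSSIndex:
    """Per-chromosome sorted TSS positions with gene back-references."""

    def __init__(self, models: Sequence[GeneModel]):
        self.models = tuple(models)
        self._by_chrom: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
        grouped: dict[str, list[GeneModel]] = {}
        for g in models:
            grouped.setdefault(g.chrom, []).append(g)
        for chrom, genes in grouped.items():
            genes.sort(key=lambda g: (g.tss, g.gene_id))
            self._by_chrom[chrom] = (
                np.array([g.tss for g in genes], dtype=np.int64),
                genes,
            )

    def nearest(self, chrom: str, position: int) -> Optional[tuple[GeneModel, int]]:
        """Nearest gene by |TSS - position|; returns (gene, signed distance).

        Equidistant TSSs break by lexicographic gene id.  The sign follows
        the winning gene's orientation.
        """
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        positions, genes = entry
        i = int(np.searchsorted(positions, position))
        # candidate block: neighbours of the insertion point, expanded over
        # runs of identical TSS values so gene-id tie-breaking sees them all
        cand_idx = set()
        for j in (i - 1, i):
            if 0 <= j < len(genes):
                cand_idx.add(j)
                k = j
                while k - 1 >= 0 and positions[k - 1] == positions[j]:
                    k -= 1
                    cand_idx.add(k)
                k = j
                while k + 1 < len(genes) and positions[k + 1] == positions[j]:
                    k += 1
                    cand_idx.add(k)
        best = min(
            cand_idx,
            key=lambda j: (abs(int(positions[j]) - position), genes[j].gene_id),
        )
        gene = genes[best]
        signed = (
            position - gene.tss if gene.strand == "+" else gene.tss - position
        )
        return gene, signed


def classify_peak(
    peak: Peak,
    index: TSSIndex,
    promoter_window: int = 4000,
    tts_window: int = 1000,
) -> FeatureCall:
    """Assign the peak one feature category against its nearest gene."""
    hit = index.nearest(peak.chrom, peak.midpoint)
    if hit is None:
        return FeatureCall(peak, "intergenic", None, None)
    gene, signed = hit
    mid = peak.midpoint
    if abs(signed) <= promoter_window:
        return FeatureCall(peak, "promoter-TSS", gene.gene_id, signed)
    if abs(mid - gene.tes) <= tts_window:
        return FeatureCall(peak, "TTS", gene.gene_id, signed)
    # UTR categories need CDS bounds, absent from the reduced model: folded
    # into "exon" by documented convention.
    if any(s <= mid < e for s, e in gene.exons):
        return FeatureCall(peak, "exon", gene.gene_id, signed)
    lo, hi = gene.span
    if lo <= mid < hi:
        return FeatureCall(peak, "intron", gene.gene_id, signed)
    return FeatureCall(peak, "intergenic", gene.gene_id, signed)


def classify_peaks(
    peaks: PeakSet,
    models: Sequence[GeneModel],
    promoter_window: int = 4000,
    tts_window: int = 1000,
) -> list[FeatureCall]:
    index = TSSIndex(models)
    return [classify_peak(p, index, promoter_window, tts_window) for p in peaks]


def tss_window_fraction(
    peaks: PeakSet,
    models: Sequence[GeneModel],
    windows: Sequence[int],
) -> dict[int, float]:
    """Fraction of peaks whose midpoint lies within +/- w of the nearest TSS.

    ``windows`` must be sorted ascending; the result is monotone
    non-decreasing in the window size by construction.  Peaks on chromosomes
    with no gene count as outside every window.
    """
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    if list(windows) != sorted(windows):
        raise ValueError("windows must be sorted ascending")
    index = TSSIndex(models)
    abs_dists = []
    for p in peaks:
        hit = index.nearest(p.chrom, p.midpoint)
        abs_dists.append(np.inf if hit is None else abs(hit[1]))
    abs_dists = np.array(abs_dists)
    return {int(w): float((abs_dists <= w).mean()) for w in windows}
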