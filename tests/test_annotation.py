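"""Feature classification priority rules and TSS-window statistics."""

import numpy as np
import pytest

from broaddomain.annotation import (
    GeneModel,
    TSSIndex,
    classify_peak,
    classify_peaks,
    tss_window_fraction,
)
from broaddomain.core_intervals import Peak, PeakSet


def oracle_classify(peak, genes, promoter_window=4000, tts_window=1000):
    """Independent re-implementation of the priority table by plain loops."""
    mid = (peak.start + peak.end) // 2
    on_chrom = [g for g in genes if g.chrom == peak.chrom]
    if not on_chrom:
        return "intergenic", None
    best = min(on_chrom, key=lambda g: (abs(g.tss - mid), g.gene_id))
    signed = mid - best.tss if best.strand == "+" else best.tss - mid
    if abs(signed) <= promoter_window:
        return "promoter-TSS", signed
    if abs(mid - best.tes) <= tts_window:
        return "TTS", signed
    if any(s <= mid < e for s, e in best.exons):
        return "exon", signed
    lo, hi = min(best.tss, best.tes), max(best.tss, best.tes)
    if lo <= mid < hi:
        return "intron", signed
    return "intergenic", signed


def random_gene(rng, chrom, chrom_len):
    tss = int(rng.integers(10_000, chrom_len - 60_000))
    strand = "+" if rng.random() < 0.5 else "-"
    glen = int(rng.integers(8_000, 50_000))
    tes = tss + glen if strand == "+" else tss - glen
    lo, hi = min(tss, tes), max(tss, tes)
    third = (hi - lo) // 3
    exons = ((lo, lo + third // 2), (lo + third, lo + 2 * third), (hi - third // 2, hi))
    return GeneModel(f"g{rng.integers(1e6):06d}", chrom, strand, tss, tes, exons)


class TestClassifyPeak:
    def test_promoter_upstream_of_plus_strand_tss(self):
        gene = GeneModel("gA", "chr1", "+", 10_000, 30_000)
        call = classify_peak(Peak("chr1", 9_400, 9_600), TSSIndex([gene]))
        assert call.category == "promoter-TSS"
        assert call.tss_distance == -500

    def test_gene_free_chromosome_is_intergenic(self):
        gene = GeneModel("gA", "chr2", "+", 10_000, 30_000)
        call = classify_peak(Peak("chr1", 100, 300), TSSIndex([gene]))
        assert call.category == "intergenic"
        assert call.gene_id is None and call.tss_distance is None

    def test_tts_beats_gene_body(self):
        gene = GeneModel("gA", "chr1", "+", 0, 30_000)
        call = classify_peak(Peak("chr1", 29_500, 30_100), TSSIndex([gene]))
        assert call.category == "TTS"

    def test_intron_inside_body_outside_exons(self):
        gene = GeneModel("gA", "chr1", "+", 0, 30_000, ((0, 1000), (28_000, 30_000)))
        call = classify_peak(Peak("chr1", 14_000, 16_000), TSSIndex([gene]))
        assert call.category == "intron"

    def test_equidistant_tie_breaks_by_gene_id(self):
        ga = GeneModel("gB", "chr1", "+", 10_000, 20_000)
        gb = GeneModel("gA", "chr1", "+", 30_000, 40_000)
        # midpoint at 20_000: both TSSs are 10 kb away
        call = classify_peak(Peak("chr1", 19_000, 21_000), TSSIndex([ga, gb]),
                             promoter_window=12_000)
        assert call.gene_id == "gA"

    def test_matches_priority_oracle_on_random_instances(self):
        rng = np.random.default_rng(200)
        chroms = {"chr1": 500_000, "chr2": 400_000}
        genes = [random_gene(rng, c, l) for c, l in chroms.items() for _ in range(10)]
        peaks = []
        for _ in range(200):
            chrom = "chr1" if rng.random() < 0.5 else "chr2"
            start = int(rng.integers(0, chroms[chrom] - 3000))
            peaks.append(Peak(chrom, start, start + int(rng.integers(500, 3000))))
        calls = classify_peaks(PeakSet(peaks), genes)
        for call in calls:
            cat, signed = oracle_classify(call.peak, genes)
            assert call.category == cat
            assert call.tss_distance == signed

    def test_every_peak_gets_exactly_one_category(self, rng):
        genes = [random_gene(rng, "chr1", 500_000) for _ in range(5)]
        peaks = PeakSet([Peak("chr1", i * 2000, i * 2000 + 900) for i in range(100)])
        calls = classify_peaks(peaks, genes)
        assert len(calls) == len(peaks)
        valid = {"promoter-TSS", "TTS", "5'UTR", "exon", "intron", "3'UTR", "intergenic"}
        assert all(c.category in valid for c in calls)


class TestTssWindowFraction:
    def test_all_peaks_on_tss(self):
        genes = [GeneModel(f"g{i}", "chr1", "+", i * 50_000 + 25_000, i * 50_000 + 40_000)
                 for i in range(5)]
        peaks = PeakSet([Peak("chr1", g.tss - 500, g.tss + 500) for g in genes])
        fr = tss_window_fraction(peaks, genes, [1000, 2000, 4000])
        assert all(v == 1.0 for v in fr.values())

    def test_no_gene_within_reach(self):
        genes = [GeneModel("gA", "chr1", "+", 2_000_000, 2_050_000)]
        peaks = PeakSet([Peak("chr1", 100, 1100)])
        fr = tss_window_fraction(peaks, genes, [1000, 100_000])
        assert fr[1000] == 0.0 and fr[100_000] == 0.0

    def test_monotone_in_window(self, rng):
        genes = [random_gene(rng, "chr1", 1_000_000) for _ in range(20)]
        peaks = PeakSet([
            Peak("chr1", int(s), int(s) + 1000)
            for s in rng.integers(0, 990_000, size=300)
        ])
        fr = tss_window_fraction(peaks, genes, [1000, 2000, 3000, 4000, 10_000])
        values = list(fr.values())
        assert values == sorted(values)

    def test_planted_proximity_recovered(self, default_universe):
        from broaddomain.breadth_rank import select_broadest

        u = default_universe
        top, _ = select_broadest(u.cohorts["cohort1"], u.config.broadest_fraction)
        fr = tss_window_fraction(top, u.gene_models, [4000])
        assert fr[4000] == pytest.approx(u.config.tss_proximity_broad, abs=0.02)

    def test_empty_peaks_rejected(self):
        with pytest.raises(ValueError):
            tss_window_fraction(PeakSet([]), [], [1000])
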