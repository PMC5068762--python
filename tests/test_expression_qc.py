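"""Paired compartment testing and Spearman sample QC."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from broaddomain.expression_qc import (
    ExpressionMatrix,
    paired_compartment_test,
    peak_coverage_features,
    sample_correlation,
)
from broaddomain.annotation import GeneModel
from broaddomain.core_intervals import Peak, PeakSet
from broaddomain.synthetic_data import SyntheticConfig, generate_expression


def make_matrix(gray, white, gene_prefix="g"):
    """Matrix with n_pairs subjects from per-gene gray/white target means."""
    genes = [f"{gene_prefix}{i}" for i in range(len(gray))]
    cols, meta = {}, []
    for j in range(6):
        cols[f"s{j}_g"] = np.asarray(gray, dtype=float)
        cols[f"s{j}_w"] = np.asarray(white, dtype=float)
        meta.append((f"s{j}_g", f"s{j}", "gray"))
        meta.append((f"s{j}_w", f"s{j}", "white"))
    values = pd.DataFrame(cols, index=genes)
    meta = pd.DataFrame(meta, columns=["sample", "subject", "compartment"]).set_index("sample")
    return ExpressionMatrix(values=values, meta=meta)


def exact_signed_rank_p(diffs):
    """Enumerate all sign assignments of |d| ranks; two-sided exact p."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    ranks = sps.rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    n = len(d)
    total = 0
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        # two-sided: as or more extreme in distance from the mean n(n+1)/4
        if abs(w - n * (n + 1) / 4) >= abs(w_pos - n * (n + 1) / 4) - 1e-9:
            count += 1
    return count / total


class TestPairedCompartmentTest:
    def test_no_signal_error_when_compartments_identical(self):
        expr = make_matrix([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="no signal"):
            paired_compartment_test(expr)

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(8)
        gray = rng.lognormal(1, 0.5, 30)
        white = rng.lognormal(0.5, 0.5, 30)
        expr = make_matrix(gray, white)
        flipped = make_matrix(white, gray)
        a = paired_compartment_test(expr)
        b = paired_compartment_test(flipped)
        assert a.p_value == pytest.approx(b.p_value)
        assert a.median_log2_ratio == pytest.approx(-b.median_log2_ratio)

    def test_matches_exact_enumeration_small_n(self):
        rng = np.random.default_rng(14)
        for _ in range(10):
            n = int(rng.integers(6, 15))
            gray = rng.lognormal(1, 0.6, n)
            white = rng.lognormal(1, 0.6, n)
            expr = make_matrix(gray, white)
            res = paired_compartment_test(expr)
            assert res.p_value == pytest.approx(exact_signed_rank_p(gray - white),
                                                abs=1e-10)

    def test_planted_effect_is_detected(self):
        cfg = SyntheticConfig(seed=9, expr_effect_log2=1.0, expr_noise_sd=0.5,
                              n_expr_pairs=6)
        gene_ids = [f"g{i:04d}" for i in range(600)]
        targets = gene_ids[:475]
        expr, _ = generate_expression(cfg, gene_ids, targets)
        res = paired_compartment_test(expr, targets)
        assert res.p_value < 1e-4
        assert res.median_log2_ratio > 0.5
        assert res.n_pairs == 6

    def test_null_effect_p_calibration(self):
        gene_ids = [f"g{i:03d}" for i in range(50)]
        hits = 0
        reps = 500
        for seed in range(reps):
            cfg = SyntheticConfig(seed=seed, expr_effect_log2=0.0, n_expr_pairs=6)
            expr, _ = generate_expression(cfg, gene_ids, gene_ids)
            if paired_compartment_test(expr, gene_ids).p_value < 0.05:
                hits += 1
        assert 0.02 <= hits / reps <= 0.08

    def test_too_few_pairs_rejected(self):
        expr = make_matrix([1, 2], [2, 3])
        expr.meta = expr.meta.iloc[:2]
        expr.values = expr.values.iloc[:, :2]
        with pytest.raises(ValueError):
            paired_compartment_test(expr)


class TestSampleCorrelation:
    def test_duplicate_sample_correlates_perfectly(self, rng):
        X = pd.DataFrame(rng.random((3, 20)), index=["a", "b", "c"])
        X.loc["b"] = X.loc["a"]
        corr = sample_correlation(X)
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_rank_reversal_gives_minus_one(self, rng):
        base = rng.random(30)
        X = pd.DataFrame([base, -base], index=["a", "rev"])
        assert sample_correlation(X).loc["a", "rev"] == pytest.approx(-1.0)

    def test_monotone_transform_invariance(self, rng):
        X = pd.DataFrame(rng.random((4, 25)), index=list("abcd"))
        Y = X.copy()
        Y.loc["a"] = np.exp(3 * Y.loc["a"]) + 7  # strictly increasing transform
        a = sample_correlation(X)
        b = sample_correlation(Y)
        pd.testing.assert_frame_equal(a, b)

    def test_matches_rank_then_pearson_oracle(self, rng):
        X = pd.DataFrame(rng.integers(0, 10, size=(5, 30)).astype(float))
        corr = sample_correlation(X)
        for i in range(5):
            for j in range(5):
                ri = sps.rankdata(X.iloc[i])
                rj = sps.rankdata(X.iloc[j])
                assert corr.iloc[i, j] == pytest.approx(np.corrcoef(ri, rj)[0, 1])

    def test_constant_sample_is_undefined(self, rng):
        X = pd.DataFrame(rng.random((3, 10)), index=["a", "b", "flat"])
        X.loc["flat"] = 5.0
        corr = sample_correlation(X)
        assert np.isnan(corr.loc["flat", "a"])
        assert corr.loc["a", "b"] == corr.loc["b", "a"]

    def test_block_structure_within_exceeds_between(self, rng):
        # two cell types with a shared profile per type plus noise
        type_a = rng.random(200) * 10
        type_b = rng.random(200) * 10
        rows, labels = [], []
        for i in range(4):
            rows.append(type_a + rng.normal(0, 0.5, 200))
            labels.append(f"a{i}")
        for i in range(4):
            rows.append(type_b + rng.normal(0, 0.5, 200))
            labels.append(f"b{i}")
        corr = sample_correlation(pd.DataFrame(rows, index=labels))
        within, between = [], []
        for i in labels:
            for j in labels:
                if i < j:
                    (within if i[0] == j[0] else between).append(corr.loc[i, j])
        assert np.mean(within) > np.mean(between)


class TestPeakCoverageFeatures:
    def test_coverage_counts_overlap_bp(self):
        models = [GeneModel("gA", "chr1", "+", 10_000, 20_000)]
        ps = PeakSet([Peak("chr1", 9_000, 11_000), Peak("chr1", 50_000, 51_000)])
        feats = peak_coverage_features({"s1": ps}, models, flank=4000)
        # window [6000, 24000): first peak fully inside -> 2000 bp
        assert feats.loc["s1", "gA"] == 2000
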