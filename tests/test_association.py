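"""Pairwise OLS screen, BH step-up, and distance binning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stagenet.annotations import FeatureAnnotation, FeatureAnnotationSet
from stagenet.association import (
    DISTANCE_BINS,
    P_FLOOR,
    AssociationRecord,
    bh_fdr,
    classify_distance,
    fit_pair,
    run_stage,
    summarize_bins,
)

from conftest import make_matrix


def naive_ols(x, y):
    """Independent per-pair OLS oracle via the closed-form normal equations."""
    n = len(x)
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    beta = sxy / sxx
    resid = (y - y.mean()) - beta * (x - x.mean())
    se = np.sqrt(resid @ resid / (n - 2) / sxx)
    t = beta / se
    return beta, t, 2 * stats.t.sf(abs(t), n - 2)


class TestFitPair:
    def test_hand_computed_example(self):
        # x=[1..5], y=[2,1,4,3,5]: r^2 = 0.64, t = sqrt(0.64*3/0.36)
        beta, t, p = fit_pair(np.arange(1.0, 6.0), np.array([2.0, 1.0, 4.0, 3.0, 5.0]))
        assert beta == pytest.approx(0.8, abs=1e-12)
        assert t == pytest.approx(np.sqrt(0.64 * 3 / 0.36), abs=1e-9)
        assert p == pytest.approx(0.104, abs=5e-4)

    def test_perfect_fit_clamps_p(self):
        x = np.arange(10.0)
        beta, t, p = fit_pair(x, 2 * x)
        assert beta == pytest.approx(2.0)
        assert p == P_FLOOR

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError):
            fit_pair(np.ones(5), np.arange(5.0))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_pair(np.array([1.0, 2.0]), np.array([1.0, 2.0]))

    def test_negating_response_flips_beta_keeps_p(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=12), rng.normal(size=12)
        b1, t1, p1 = fit_pair(x, y)
        b2, t2, p2 = fit_pair(x, -y)
        assert b2 == pytest.approx(-b1)
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        x, y = rng.normal(size=20), rng.normal(size=20)
        beta, t, p = fit_pair(x, y)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert beta == pytest.approx(fit.params[1], abs=1e-10)
        assert t == pytest.approx(fit.tvalues[1], abs=1e-8)
        assert p == pytest.approx(fit.pvalues[1], abs=1e-10)


class TestBH:
    def test_hand_step_up_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_is_itself(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        assert (bh_fdr([1.0, 1.0, 1.0]) == 1.0).all()

    def test_out_of_range_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], [np.nan, 0.5]):
            with pytest.raises(ValueError):
                bh_fdr(bad)

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(1e-8, 1, size=rng.integers(1, 200))
            q = bh_fdr(p)
            _, q_ref, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(q, q_ref, atol=1e-12)

    def test_q_order_never_inverts_p_order(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=100)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestRunStage:
    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(3)
        n = 15
        mirna = make_matrix(rng.normal(size=(20, n)))
        gene = make_matrix(rng.normal(size=(30, n)),
                           feature_ids=[f"g{i}" for i in range(30)])
        records = run_stage(mirna, gene, "I", fdr=1.0)
        assert len(records) == 20 * 30
        by_pair = {(r.mirna_id, r.gene_id): r for r in records}
        X = mirna.values.to_numpy()
        Y = gene.values.to_numpy()
        for i in range(20):
            for j in range(30):
                beta, t, p = naive_ols(X[i], Y[j])
                r = by_pair[(f"f{i}", f"g{j}")]
                assert r.beta == pytest.approx(beta, abs=1e-10)
                assert r.t_stat == pytest.approx(t, abs=1e-10)
                assert r.p_value == pytest.approx(p, abs=1e-10)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(5)
        mirna = make_matrix(rng.normal(size=(100, 40)))
        gene = make_matrix(rng.normal(size=(100, 40)),
                           feature_ids=[f"g{i}" for i in range(100)])
        records = run_stage(mirna, gene, "I", fdr=1.0)
        pvals = [r.p_value for r in records]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_pairing_invariance_under_shared_permutation(self):
        rng = np.random.default_rng(6)
        mirna = make_matrix(rng.normal(size=(5, 12)))
        gene = make_matrix(rng.normal(size=(8, 12)), feature_ids=[f"g{i}" for i in range(8)])
        ref = run_stage(mirna, gene, "I", fdr=1.0)
        perm = list(rng.permutation(mirna.sample_ids))
        ref2 = run_stage(mirna.subset_samples(perm), gene.subset_samples(perm), "I", fdr=1.0)
        for a, b in zip(ref, ref2):
            assert (a.mirna_id, a.gene_id) == (b.mirna_id, b.gene_id)
            assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_q_values_reproducible_from_p(self):
        rng = np.random.default_rng(9)
        mirna = make_matrix(rng.normal(size=(6, 10)))
        gene = make_matrix(rng.normal(size=(7, 10)), feature_ids=[f"g{i}" for i in range(7)])
        records = run_stage(mirna, gene, "I", fdr=1.0)
        q_re = bh_fdr([r.p_value for r in records])
        np.testing.assert_allclose([r.q_value for r in records], q_re, atol=1e-12)

    def test_too_few_samples_refused(self):
        mirna = make_matrix(np.ones((2, 3)) + np.arange(3))
        gene = make_matrix(np.ones((2, 3)), feature_ids=["g0", "g1"])
        with pytest.raises(ValueError, match="samples"):
            run_stage(mirna, gene, "I")

    def test_mismatched_samples_rejected(self):
        mirna = make_matrix(np.ones((2, 5)))
        gene = make_matrix(np.ones((2, 5)), feature_ids=["g0", "g1"],
                           sample_ids=[f"t{j}" for j in range(5)])
        with pytest.raises(ValueError, match="samples"):
            run_stage(mirna, gene, "I")


def ann(fid, chrom, start, end, fclass="gene"):
    return FeatureAnnotation(id=fid, chrom=chrom, start=start, end=end, feature_class=fclass)


class TestDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (ann("m", "chr1", 500_000, 500_100, "miRNA"), ann("g", "chr1", 900_000, 905_000), "(0,1MB]"),
            (ann("m", "chr1", 1, 100, "miRNA"), ann("g", "chr2", 1, 100), "CrossChr"),
            # overlap -> gap 0 -> first bin
            (ann("m", "chr1", 100, 5000, "miRNA"), ann("g", "chr1", 400, 900), "(0,1MB]"),
            # gap exactly 1e6 stays in the first (upper-inclusive) bin
            (ann("m", "chr1", 1, 100, "miRNA"), ann("g", "chr1", 1_000_101, 1_000_200), "(0,1MB]"),
            (ann("m", "chr1", 1, 100, "miRNA"), ann("g", "chr1", 1_000_102, 1_000_200), "(1,10MB]"),
            (ann("m", "chr1", 1, 100, "miRNA"), ann("g", "chr1", 30_000_000, 30_000_100), "(10,50MB]"),
            (ann("m", "chr1", 1, 100, "miRNA"), ann("g", "chr1", 90_000_000, 90_000_100), "(50,100MB]"),
            (ann("m", "chr1", 1, 100, "miRNA"), ann("g", "chr1", 150_000_000, 150_000_100), "(100,200MB]"),
            (ann("m", "chr1", 1, 100, "miRNA"), ann("g", "chr1", 220_000_000, 220_000_100), ">200MB"),
        ],
    )
    def test_binning(self, a, b, expected):
        assert classify_distance(a, b) == expected

    def test_symmetric(self):
        a = ann("m", "chr1", 10, 100, "miRNA")
        b = ann("g", "chr1", 5_000_000, 5_001_000)
        assert classify_distance(a, b) == classify_distance(b, a)


class TestSummarizeBins:
    def test_empty_input_gives_empty_table(self):
        table = summarize_bins([])
        assert table.shape == (0, len(DISTANCE_BINS))

    def test_counts_and_conservation(self):
        recs = [
            AssociationRecord("m1", "g1", "I", 1, 1, 0.01, 0.01, "CrossChr"),
            AssociationRecord("m1", "g2", "I", 1, 1, 0.01, 0.01, "CrossChr"),
            AssociationRecord("m2", "g3", "I", 1, 1, 0.01, 0.01, "CrossChr"),
            AssociationRecord("m2", "g4", "II", 1, 1, 0.01, 0.01, "(0,1MB]"),
            AssociationRecord("m2", "g5", "II", 1, 1, 0.01, 0.01, None),  # unannotated
        ]
        table = summarize_bins(recs)
        assert table.loc["I", "CrossChr"] == 3
        assert table.loc["II", "(0,1MB]"] == 1
        annotated = sum(1 for r in recs if r.distance_bin is not None)
        assert table.to_numpy().sum() == annotated
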