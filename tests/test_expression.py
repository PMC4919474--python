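"""Expression cutoff, replicate QC, DE calls, signatures, enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from ldscreen.expression import (
    de_burden_compare,
    de_test,
    expressed_genes,
    expression_cutoff,
    replicate_qc,
    set_enrichment,
    signature_clusters,
)
from ldscreen.simulate import simulate_expression

from conftest import build_expression_matrix


class TestExpressionCutoff:
    def test_order_statistic_oracle(self):
        # intergenic values 0.01..1.00: interpolated 95th percentile sits
        # between 0.95 and 1.00
        inter = np.array([0.01 * k for k in range(1, 101)]).reshape(-1, 1)
        m = build_expression_matrix(
            np.vstack([np.ones((2, 1)), inter]),
            ["A"],
            kinds=["genic"] * 2 + ["intergenic"] * 100,
        )
        thr = expression_cutoff(m)
        assert 0.95 <= thr <= 1.00
        # exact linear-interpolation value on this grid
        assert thr == pytest.approx(np.percentile(inter, 95))

    def test_all_zero_background_filters_nothing(self):
        vals = np.vstack([np.full((3, 2), 5.0), np.zeros((25, 2))])
        m = build_expression_matrix(
            vals, ["A", "A"], kinds=["genic"] * 3 + ["intergenic"] * 25
        )
        assert expression_cutoff(m) == 0.0
        assert len(expressed_genes(m, 0.0)) == 3

    def test_no_intergenic_features_is_an_error(self):
        m = build_expression_matrix(np.ones((3, 2)), ["A", "A"])
        with pytest.raises(ValueError, match="intergenic"):
            expression_cutoff(m)

    def test_monotone_in_percentile_and_filter_keeps_high_genes(self):
        m, _ = simulate_expression(n_genes=50, n_intergenic=200, seed=0)
        t90 = expression_cutoff(m, 90)
        t95 = expression_cutoff(m, 95)
        t99 = expression_cutoff(m, 99)
        assert t90 <= t95 <= t99
        kept = expressed_genes(m, t95)
        assert (m.values.loc[kept].max(axis=1) >= t95).all()

    def test_background_calibrated_to_reported_cutoff(self):
        # the generator pins the pooled intergenic 95th percentile, so the
        # cutoff reproduces the published 1.04 FPKM threshold exactly
        m, _ = simulate_expression(seed=3, intergenic_q95=1.04)
        assert expression_cutoff(m, 95) == pytest.approx(1.04, abs=1e-9)


class TestReplicateQC:
    def test_monotone_transform_preserves_all_replicates(self):
        rng = np.random.default_rng(0)
        base = rng.lognormal(1, 1, size=(80, 1))
        # replicates are monotone transforms of one profile: Spearman 1
        vals = np.hstack([base, base**2, np.sqrt(base), base, base * 3 + 1, base**1.5])
        m = build_expression_matrix(vals, ["A"] * 3 + ["B"] * 3)
        retained, rho = replicate_qc(m)
        assert len(retained) == 6
        assert rho.min().min() == pytest.approx(1.0)

    def test_permuted_replicate_dropped(self):
        rng = np.random.default_rng(1)
        base = rng.lognormal(1, 1, size=200)
        cols = [base, base * 1.01, rng.permutation(base), base, base * 0.99]
        m = build_expression_matrix(np.column_stack(cols), ["A"] * 3 + ["B"] * 2)
        retained, _ = replicate_qc(m)
        assert "A_r3" not in retained
        assert len(retained) == 4

    def test_condition_never_drops_below_two(self):
        rng = np.random.default_rng(2)
        vals = rng.lognormal(1, 1, size=(100, 4))  # mutually uncorrelated
        m = build_expression_matrix(vals, ["A"] * 2 + ["B"] * 2)
        with pytest.warns(UserWarning, match="best 2"):
            retained, _ = replicate_qc(m)
        assert len(retained) == 4

    def test_single_replicate_condition_rejected(self):
        m = build_expression_matrix(np.ones((5, 3)), ["A", "A", "B"])
        with pytest.raises(ValueError, match="B"):
            replicate_qc(m)


class TestDETest:
    def test_identical_conditions_find_nothing(self):
        rng = np.random.default_rng(3)
        half = rng.lognormal(2, 1, size=(100, 3))
        m = build_expression_matrix(np.hstack([half, half]), ["A"] * 3 + ["B"] * 3)
        de = de_test(m, "A", "B")
        assert int(de["significant"].sum()) == 0

    def test_planted_fourfold_shift_recovered(self):
        rng = np.random.default_rng(4)
        n_de, n_null = 50, 1000
        base = rng.normal(3, 1, size=(n_de + n_null, 1))
        log2 = base + rng.normal(0, 0.02, size=(n_de + n_null, 6))
        log2[:n_de, :3] += 2.0  # 4-fold shift in condition A
        m = build_expression_matrix(np.power(2.0, log2), ["A"] * 3 + ["B"] * 3)
        de = de_test(m, "A", "B", alpha=0.001)
        assert de["significant"][:n_de].all()
        # false positives bounded by the null binomial's upper tail
        fp_limit = stats.binom.ppf(0.99, n_null, 0.001)
        assert int(de["significant"][n_de:].sum()) <= fp_limit
        # the +1 pseudocount shrinks the planted 2-unit shift slightly
        assert 1.5 <= de["log2fc"][:n_de].mean() <= 2.0
        assert abs(de["log2fc"][n_de:].mean()) < 0.05

    def test_constant_gene_gets_p_one(self):
        vals = np.vstack([np.full((1, 6), 7.0), np.ones((1, 6))])
        m = build_expression_matrix(vals, ["A"] * 3 + ["B"] * 3)
        de = de_test(m, "A", "B")
        assert (de["p_value"] == 1.0).all()

    def test_null_pvalues_uniform(self):
        # Welch t on log-normal noise, 5 vs 5 replicates, 5000 null genes
        rng = np.random.default_rng(0)
        n = 5000
        log2 = rng.normal(3, 1, size=(n, 1)) + rng.normal(0, 0.25, size=(n, 10))
        m = build_expression_matrix(np.power(2.0, log2), ["A"] * 5 + ["B"] * 5)
        de = de_test(m, "A", "B", alpha=0.001)
        assert stats.kstest(de["p_value"], "uniform").pvalue > 0.01
        n_sig = int(de["significant"].sum())
        assert abs(n_sig - 0.001 * n) <= 3 * math.sqrt(n * 0.001 * 0.999) + 1


class TestSignatureClusters:
    def test_planted_orthogonal_profiles_fully_recovered(self):
        m, truth = simulate_expression(
            n_genes=200, n_intergenic=50, k_clusters=5, effect=3.0,
            noise_sd=0.05, seed=5,
        )
        genes = truth.index[truth["cluster"] >= 0]
        labels = signature_clusters(m, genes, k=5, seed=0)
        assert adjusted_rand_score(truth.loc[labels.index, "cluster"], labels) == 1.0

    def test_deterministic_given_seed(self):
        m, truth = simulate_expression(n_genes=60, n_intergenic=30, seed=6)
        genes = truth.index[truth["cluster"] >= 0]
        a = signature_clusters(m, genes, k=5, seed=11)
        b = signature_clusters(m, genes, k=5, seed=11)
        assert a.equals(b)

    def test_sample_order_invariance(self):
        m, truth = simulate_expression(n_genes=60, n_intergenic=30, seed=7)
        genes = truth.index[truth["cluster"] >= 0]
        a = signature_clusters(m, genes, k=3, seed=0)
        shuffled = m.subset_samples(list(reversed(list(m.values.columns))))
        b = signature_clusters(shuffled, genes, k=3, seed=0)
        assert a.equals(b)

    def test_k_one_puts_everything_together(self):
        m, truth = simulate_expression(n_genes=30, n_intergenic=30, seed=8)
        labels = signature_clusters(m, truth.index[truth["cluster"] >= 0], k=1, seed=0)
        assert (labels == 0).all()

    def test_zero_variance_gene_excluded_with_warning(self):
        m, truth = simulate_expression(n_genes=30, n_intergenic=30, seed=9)
        flat = m.values.index[0]
        m.values.loc[flat] = 5.0
        with pytest.warns(UserWarning, match="zero variance"):
            labels = signature_clusters(m, list(truth.index[truth["cluster"] >= 0]), k=3, seed=0)
        assert flat not in labels.index


class TestDEBurden:
    def test_identical_vectors_give_p_one(self):
        v = np.abs(np.random.default_rng(0).normal(1, 0.5, 50))
        assert de_burden_compare(v, v) == 1.0

    def test_constant_shift_detected(self):
        rng = np.random.default_rng(1)
        inactive = np.abs(rng.normal(0.5, 0.2, 100))
        assert de_burden_compare(inactive + 1.0, inactive) < 1e-10

    def test_matches_exact_enumeration_oracle(self):
        # 10 paired differences with magnitudes ranking 1..10, one negative
        # at rank 1: enumerate all 2^10 sign patterns for the exact null
        diffs = np.array([-1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10])
        inactive = np.full(10, 5.0)
        active = inactive + diffs
        ranks = stats.rankdata(np.abs(diffs))
        w_obs = min(ranks[diffs > 0].sum(), ranks[diffs < 0].sum())
        count = 0
        for pattern in range(2**10):
            w_minus = sum(
                ranks[i] for i in range(10) if (pattern >> i) & 1
            )
            w = min(w_minus, 55 - w_minus)
            if w <= w_obs:
                count += 1
        exact_p = count / 2**10
        assert de_burden_compare(active, inactive) == pytest.approx(exact_p)


class TestSetEnrichment:
    def test_closed_form_extreme_overlap(self):
        universe = [f"g{i}" for i in range(20)]
        de = universe[:5]
        res = set_enrichment(de, universe, {"hit_set": de})
        assert res.loc["hit_set", "p_value"] == pytest.approx(1 / 15504, rel=1e-9)

    def test_disjoint_set_not_enriched(self):
        universe = [f"g{i}" for i in range(50)]
        res = set_enrichment(universe[:3], universe, {"other": universe[10:20]})
        assert res.loc["other", "p_value"] > 0.4

    def test_bh_hand_computation(self):
        universe = [f"g{i}" for i in range(400)]
        res = set_enrichment(
            universe[:20],
            universe,
            {"a": universe[:18], "b": universe[:120], "c": universe[300:]},
        )
        p = res["p_value"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        staged = p[order] * m / np.arange(1, m + 1)
        expected = np.minimum.accumulate(staged[::-1])[::-1]
        assert res["q_value"].to_numpy()[order] == pytest.approx(np.minimum(expected, 1.0))
        assert (res["q_value"] >= res["p_value"] - 1e-12).all()
        assert (res["q_value"] <= 1.0).all()

    def test_de_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            set_enrichment(["x"], ["a", "b"], {})

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            set_enrichment([], [], {})
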