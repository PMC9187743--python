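"""Running-sum ES, mean-rank GSA, permutation nulls and z tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ribolens.genesets import (
    GeneSetCollection,
    RankedList,
    adjust_fdr,
    attach_fdr,
    gsa_mean_rank,
    gsea_es,
    permutation_null,
    size_matched_reference,
    two_sample_z,
)


def naive_es(ordered_genes, gene_set):
    """Independent loop re-implementation of the running-sum ES."""
    n = len(ordered_genes)
    hits = [g in gene_set for g in ordered_genes]
    g = sum(hits)
    up, down = math.sqrt((n - g) / g), math.sqrt(g / (n - g))
    running, best = 0.0, 0.0
    for h in hits:
        running += up if h else -down
        if abs(running) > abs(best) or (abs(running) == abs(best) and running > best):
            best = running
    return best


def ranked_from_order(genes):
    """RankedList with the given explicit order (metric = descending index)."""
    metric = pd.Series(np.arange(len(genes), 0, -1, dtype=float), index=genes)
    return RankedList.from_metric(metric, orientation="descending")


class TestGseaEs:
    def test_top_two_of_four(self):
        # hit step sqrt((4-2)/2)=1, miss step 1: running sum 1,2,1,0 -> ES=2
        ranked = ranked_from_order(list("abcd"))
        assert gsea_es(ranked, {"a", "b"}) == pytest.approx(2.0)

    def test_bottom_mirror_has_opposite_sign(self):
        ranked = ranked_from_order(list("abcd"))
        assert gsea_es(ranked, {"c", "d"}) == pytest.approx(-2.0)

    def test_matches_naive_loop_on_random_instances(self, rng):
        genes = [f"g{i}" for i in range(50)]
        for _ in range(25):
            order = list(rng.permutation(genes))
            members = set(rng.choice(genes, size=8, replace=False))
            ranked = ranked_from_order(order)
            assert gsea_es(ranked, members) == pytest.approx(
                naive_es(order, members), rel=1e-12
            )

    def test_list_reversal_negates_es(self, rng):
        genes = [f"g{i}" for i in range(30)]
        for _ in range(10):
            ranked = ranked_from_order(list(rng.permutation(genes)))
            members = set(rng.choice(genes, size=6, replace=False))
            es = gsea_es(ranked, members)
            es_rev = gsea_es(ranked.reversed(), members)
            assert abs(es_rev) == pytest.approx(abs(es), rel=1e-12)
            mask = ranked.member_mask(members)
            path = np.where(mask, math.sqrt(24 / 6), -math.sqrt(6 / 24)).cumsum()
            if not math.isclose(path.max(), -path.min(), rel_tol=1e-9):
                assert es_rev == pytest.approx(-es, rel=1e-12)

    def test_disjoint_set_rejected(self):
        ranked = ranked_from_order(list("abcd"))
        with pytest.raises(ValueError):
            gsea_es(ranked, {"zz"})


class TestPermutationNull:
    def test_extreme_observation_hits_estimator_floor(self):
        ranked = ranked_from_order([f"g{i}" for i in range(200)])
        _, p = permutation_null(ranked, 10, n_perm=199, seed=0, statistic="es", observed=1e6)
        assert p == pytest.approx(1 / 200)

    def test_median_observation_near_one(self):
        ranked = ranked_from_order([f"g{i}" for i in range(200)])
        null, _ = permutation_null(ranked, 10, n_perm=499, seed=0, statistic="mean_rank")
        med = float(np.median(null))
        _, p = permutation_null(
            ranked, 10, n_perm=499, seed=1, statistic="mean_rank", observed=med
        )
        assert p > 0.8

    def test_fixed_seed_reproducible(self):
        ranked = ranked_from_order([f"g{i}" for i in range(100)])
        null1, _ = permutation_null(ranked, 5, n_perm=199, seed=42)
        null2, _ = permutation_null(ranked, 5, n_perm=199, seed=42)
        np.testing.assert_array_equal(null1, null2)

    def test_bad_sizes_rejected(self):
        ranked = ranked_from_order(list("abcdef"))
        with pytest.raises(ValueError):
            permutation_null(ranked, 6, n_perm=199)
        with pytest.raises(ValueError):
            permutation_null(ranked, 2, n_perm=10)


class TestGsaMeanRank:
    def test_top_ranked_set_at_floor(self):
        genes = [f"g{i:04d}" for i in range(1000)]
        ranked = ranked_from_order(genes)
        res = gsa_mean_rank(ranked, set(genes[:3]), n_perm=199, seed=0, set_name="top3")
        assert res.observed == pytest.approx(2.0)
        assert res.p_nominal == pytest.approx(1 / 200)
        assert res.direction == "up"

    def test_null_mean_matches_exchangeable_expectation(self):
        genes = [f"g{i}" for i in range(500)]
        ranked = ranked_from_order(genes)
        res = gsa_mean_rank(ranked, set(genes[100:120]), n_perm=999, seed=3)
        expected = (500 + 1) / 2
        assert abs(res.null_mean - expected) < 3 * res.null_sd / math.sqrt(999)

    def test_sampled_p_agrees_with_exhaustive_enumeration(self):
        # N=10, G=3: the exact two-sided p is computable from all C(10,3) draws
        genes = list("abcdefghij")
        ranked = ranked_from_order(genes)
        members = {"a", "c", "h"}  # ranks 1, 3, 8 -> mean 4.0
        obs = 4.0
        center = (10 + 1) / 2
        devs = [
            abs(np.mean(c) - center)
            for c in itertools.combinations(range(1, 11), 3)
        ]
        exact = np.mean([d >= abs(obs - center) - 1e-12 for d in devs])
        res = gsa_mean_rank(ranked, members, n_perm=4999, seed=5)
        assert res.observed == pytest.approx(obs)
        mc_sd = math.sqrt(exact * (1 - exact) / 4999)
        assert abs(res.p_nominal - exact) < 4 * mc_sd + 1 / 5000


class TestTwoSampleZ:
    def test_identical_groups(self):
        z, p = two_sample_z([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_large_shift_detected(self, rng):
        x = rng.normal(10, 1, 200)
        y = rng.normal(0, 1, 200)
        z, p = two_sample_z(x, y)
        assert z > 20 and p < 1e-12

    def test_matches_formula_oracle(self, rng):
        x, y = rng.normal(0.3, 1.2, 30), rng.normal(0.0, 0.8, 30)
        z, p = two_sample_z(x, y)
        z_manual = (x.mean() - y.mean()) / math.sqrt(
            x.var(ddof=1) / 30 + y.var(ddof=1) / 30
        )
        from scipy.stats import norm

        assert z == pytest.approx(z_manual, rel=1e-12)
        assert p == pytest.approx(2 * norm.sf(abs(z_manual)), rel=1e-12)

    def test_common_affine_shift_invariance(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=25)
        z1, _ = two_sample_z(x, y)
        z2, _ = two_sample_z(5 * x + 3, 5 * y + 3)
        assert z2 == pytest.approx(z1, rel=1e-9)

    def test_degenerate_equal_constant_groups(self):
        assert two_sample_z([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)


class TestSizeMatchedReference:
    def test_constant_values_give_constant_pool(self):
        values = pd.Series(1.0, index=[f"g{i}" for i in range(20)])
        pooled, means = size_matched_reference(values, {"g0", "g1"}, n_draws=50, seed=0)
        assert np.all(pooled == 1.0) and np.all(means == 1.0)

    def test_mean_of_draw_means_near_grand_mean(self, rng):
        values = pd.Series(rng.normal(size=200), index=[f"g{i}" for i in range(200)])
        _, means = size_matched_reference(values, set(values.index[:30]), n_draws=2000, seed=1)
        # loose CLT bound on the mean of per-draw means
        assert abs(means.mean() - values.mean()) < values.std() / math.sqrt(2000) * 5

    def test_small_case_matches_exhaustive_moments(self):
        # N=8, G=2: compare sampled per-draw-mean moments to full enumeration
        values = pd.Series([1, 2, 3, 4, 5, 6, 7, 8.0], index=list("abcdefgh"))
        exact_means = [
            (values[a] + values[b]) / 2 for a, b in itertools.combinations(values.index, 2)
        ]
        _, means = size_matched_reference(values, {"a", "b"}, n_draws=4000, seed=2)
        assert means.mean() == pytest.approx(np.mean(exact_means), abs=0.1)
        assert means.std() == pytest.approx(np.std(exact_means), abs=0.1)

    def test_candidate_stratum_restricts_pool(self):
        values = pd.Series(np.arange(10.0), index=[f"g{i}" for i in range(10)])
        stratum = [f"g{i}" for i in range(5)]
        pooled, _ = size_matched_reference(
            values, {"g0", "g1"}, n_draws=100, seed=0, candidates=stratum
        )
        assert pooled.max() <= 4.0


class TestAdjustFdr:
    def test_hand_computed_bh(self):
        np.testing.assert_allclose(adjust_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_all_ones(self):
        assert adjust_fdr([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(adjust_fdr([1.0, 1.0]), [1.0, 1.0])

    def test_adjusted_at_least_nominal_within_family(self, rng):
        p = rng.uniform(size=40)
        adj = adjust_fdr(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()

    def test_attach_fdr_orders_with_results(self, rng):
        genes = [f"g{i}" for i in range(100)]
        ranked = ranked_from_order(genes)
        results = [
            gsa_mean_rank(ranked, set(rng.choice(genes, 10, replace=False)), n_perm=199, seed=i)
            for i in range(5)
        ]
        attach_fdr(results)
        adj = adjust_fdr([r.p_nominal for r in results])
        assert [r.p_adjusted for r in results] == pytest.approx(list(adj))
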