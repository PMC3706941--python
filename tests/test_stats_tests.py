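import itertools

import numpy as np
import pytest
from scipy import stats as sps

import oracles
from berryplast.core_data import GeneSet
from berryplast.stats_tests import (
    benjamini_hochberg,
    hypergeometric_enrichment,
    kruskal_wallis,
    kruskal_wallis_many,
    one_way_anova_bonferroni,
    sam,
    t_test_many,
    two_group_t_test,
)
from conftest import build_matrix


class TestKruskalWallis:
    def test_all_tied_input(self):
        res = kruskal_wallis([5.0] * 9, [1, 1, 1, 2, 2, 2, 3, 3, 3])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_exact_p_matches_enumeration_oracle(self):
        values = [1, 2, 3, 4, 5, 6, 7, 8, 9]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = kruskal_wallis(values, groups, method="exact")
        assert res.p_value == pytest.approx(oracles.kw_exact_p_distinct(values, groups))

    def test_chi2_h_matches_scipy_with_and_without_ties(self):
        rng = np.random.default_rng(0)
        groups = [0] * 4 + [1] * 5 + [2] * 4
        for trial in range(5):
            vals = rng.normal(size=13)
            if trial % 2:
                vals[:4] = np.round(vals[:4])  # induce ties
            res = kruskal_wallis(vals, groups)
            ref = sps.kruskal(vals[:4], vals[4:9], vals[9:])
            assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_three_group_alpha_001_calls(self):
        # a gene with p = 0.005 clears the alpha = 0.01 screen
        H, p = kruskal_wallis_many(
            np.array([[1, 2, 3, 10, 11, 12, 20, 21, 22.0]] * 2),
            [1, 1, 1, 2, 2, 2, 3, 3, 3], method="exact")
        assert (p < 0.01).all()

    def test_single_group_is_an_error(self):
        with pytest.raises(ValueError):
            kruskal_wallis_many(np.ones((1, 3)), ["a", "a", "a"])

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 9))
        groups = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        H1, p1 = kruskal_wallis_many(X, groups)
        perm = rng.permutation(9)
        H2, p2 = kruskal_wallis_many(X[:, perm], groups[perm])
        np.testing.assert_allclose(H1, H2, rtol=1e-12)


class TestTwoGroupTTest:
    def test_identical_groups(self):
        res = two_group_t_test([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_hand_computed_pooled_formula(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        res = two_group_t_test(a + b, ["a"] * 3 + ["b"] * 3)
        assert res.statistic == pytest.approx(oracles.pooled_t(a, b), abs=1e-12)
        ref = sps.ttest_ind(a, b)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_zero_variance_unequal_means_is_flagged(self):
        res = two_group_t_test([1, 1, 1, 2, 2, 2], ["a"] * 3 + ["b"] * 3)
        assert res.p_value == 0.0
        assert res.flag == "zero_pooled_variance"

    def test_alpha_005_separates_shifted_vineyards(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 12))
        X[:25, 6:] += 3.0
        t, p, _ = t_test_many(X, ["g1"] * 6 + ["g2"] * 6)
        assert (p[:25] < 0.05).mean() >= 0.9
        assert (p[25:] < 0.05).mean() <= 0.2


class TestAnova:
    def test_matches_explicit_sums_oracle(self):
        values = [3.0, 1.0, 2.0, 5.0, 4.5, 6.0, 9.0, 8.0, 10.0]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = one_way_anova_bonferroni(values, groups, alpha=0.01, n_tests=1)
        assert res.statistic == pytest.approx(oracles.anova_f(values, groups), abs=1e-12)
        ref = sps.f_oneway(values[:3], values[3:6], values[6:])
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_bonferroni_threshold(self):
        values = [3.0, 1.0, 2.0, 5.0, 4.5, 6.0, 9.0, 8.0, 10.0]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res1 = one_way_anova_bonferroni(values, groups, alpha=0.01, n_tests=1)
        res2 = one_way_anova_bonferroni(values, groups, alpha=0.01, n_tests=10_000)
        assert res1.significant and not res2.significant

    def test_null_behaviour_over_seeds(self):
        hits = 0
        for s in range(30):
            rng = np.random.default_rng(100 + s)
            res = one_way_anova_bonferroni(rng.normal(size=9),
                                           ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
                                           alpha=0.01, n_tests=1)
            hits += res.significant
        assert hits <= 3

    def test_degenerate_equal_constant_groups(self):
        res = one_way_anova_bonferroni([2.0] * 6, ["a"] * 3 + ["b"] * 3)
        assert res.statistic == 0.0
        assert res.p_value == 1.0


class TestBenjaminiHochberg:
    def test_all_ones(self):
        np.testing.assert_array_equal(benjamini_hochberg([1.0, 1.0, 1.0]), [1, 1, 1])

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_is_identity(self):
        assert benjamini_hochberg([0.3])[0] == pytest.approx(0.3)

    def test_matches_statsmodels_and_is_monotone(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(4)
        p = rng.uniform(size=100) ** 2
        q = benjamini_hochberg(p)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_ref, rtol=1e-12)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])


class TestHypergeometricEnrichment:
    def test_category_equal_to_universe_is_certain(self):
        uni = GeneSet("u", frozenset(f"g{i}" for i in range(10)))
        study = GeneSet("s", frozenset(["g0", "g1"]))
        ann = {g: ["cat"] for g in uni.members}
        (res,) = hypergeometric_enrichment(study, uni, ann)
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_urn_matches_combinatorial_tail(self):
        # universe 20, category 5, study 5, overlap 4
        uni = GeneSet("u", frozenset(f"g{i}" for i in range(20)))
        ann = {f"g{i}": ["cat"] for i in range(5)}
        study = GeneSet("s", frozenset(["g0", "g1", "g2", "g3", "g10"]))
        (res,) = hypergeometric_enrichment(study, uni, ann, threshold=0.1)
        expect = oracles.hypergeom_tail(20, 5, 5, 4)
        assert res.p_value == pytest.approx(expect, rel=1e-12)
        assert res.significant  # p ~ 0.0003 < 0.1

    def test_study_outside_universe_is_an_error(self):
        uni = GeneSet("u", frozenset(["g0"]))
        study = GeneSet("s", frozenset(["g0", "zz"]))
        with pytest.raises(ValueError, match="zz"):
            hypergeometric_enrichment(study, uni, {})


@pytest.fixture(scope="module")
def toy():
    names = ["AM081A", "AM081B", "AM081C", "CS081A", "CS081B", "CS081C"]
    rng = np.random.default_rng(8)
    X = rng.normal(10, 0.5, size=(60, 6))
    X[:10, 3:] += 2.5
    return build_matrix(X, names), ["a"] * 3 + ["b"] * 3


class TestSam:

    def test_d_statistics_match_enumeration_oracle(self, toy):
        m, labels = toy
        res = sam(m, labels, mode="two_class", fdr_target=0.05, n_perms=1000, seed=0)
        assert res.n_permutations == 20  # all label assignments enumerated
        d_oracle = oracles.sam_d(m.values, [3, 4, 5], res.s0)
        np.testing.assert_allclose(res.d, d_oracle, rtol=1e-10)
        perm_ds = oracles.sam_enumeration(m.values, 3, res.s0)
        dbar = np.mean([np.sort(p) for p in perm_ds], axis=0)
        np.testing.assert_allclose(res.d_expected, dbar, rtol=1e-10)

    def test_fdr_at_each_delta_matches_oracle(self, toy):
        m, labels = toy
        res = sam(m, labels, mode="two_class", fdr_target=0.05, n_perms=1000, seed=0)
        perm_ds = oracles.sam_enumeration(m.values, 3, res.s0)
        for delta in [0.05, 0.2, 0.5, 1.0, 2.0]:
            expect_fdr, expect_called = oracles.sam_fdr_at_delta(
                res.d, perm_ds, delta, pi0=res.pi0)
            got_fdr, got_called = res.fdr_at(delta)
            assert got_called == expect_called
            assert got_fdr == pytest.approx(expect_fdr, rel=1e-9)

    def test_called_set_shrinks_as_delta_grows(self, toy):
        m, labels = toy
        res = sam(m, labels, mode="two_class", fdr_target=0.05, n_perms=1000, seed=0)
        called = [res.fdr_at(d)[1] for d in np.linspace(0.01, 3, 25)]
        assert (np.diff(called) <= 0).all()

    def test_null_labels_call_nothing_at_strict_fdr(self):
        names = ["AM081A", "AM081B", "AM081C", "CS081A", "CS081B", "CS081C"]
        empties = 0
        for s in range(5):
            X = np.random.default_rng(200 + s).normal(10, 0.5, size=(500, 6))
            res = sam(build_matrix(X, names), ["a"] * 3 + ["b"] * 3,
                      mode="two_class", fdr_target=0.001, n_perms=100, seed=s)
            empties += len(res.significant) == 0
        assert empties >= 4

    def test_multiclass_reduces_to_absolute_two_class_d(self, toy):
        m, labels = toy
        res2 = sam(m, labels, mode="two_class", fdr_target=0.05, n_perms=50, seed=0)
        resm = sam(m, labels, mode="multiclass", fdr_target=0.05, n_perms=50, seed=0)
        # numerator/denominator identity: |d_two| = d_multi for equal s0
        d2 = oracles.sam_d(m.values, [3, 4, 5], resm.s0)
        np.testing.assert_allclose(resm.d, np.abs(d2), rtol=1e-10)

    def test_multiclass_recovers_planted_stage_effects(self, small_dataset):
        m, tt = small_dataset
        res = sam(m, [s.stage for s in m.samples], mode="multiclass",
                  fdr_target=0.001, n_perms=60, seed=3)
        markers = tt.genes_of("marker_up") | tt.genes_of("marker_down")
        assert len(res.significant.members & markers) / len(markers) >= 0.9
        false = res.significant.members - markers
        assert len(false) / max(len(res.significant), 1) <= 0.1

    def test_deterministic_under_seed(self, toy):
        m, labels = toy
        a = sam(m, labels, fdr_target=0.01, n_perms=15, seed=5)
        b = sam(m, labels, fdr_target=0.01, n_perms=15, seed=5)
        assert a.significant.members == b.significant.members
        np.testing.assert_array_equal(a.d, b.d)
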