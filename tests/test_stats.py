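"""Permutation tests and FDR control, checked against independent oracles:

- exhaustive enumeration for p-values,
- a brute-force threshold scan for dsFDR,
- statsmodels and a naive O(m^2) step-up for BH.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

import abundex as ax
from abundex import ValidationError
from abundex.stats import (
    EXHAUSTIVE_CAP,
    TestSpec,
    bh_control,
    dsfdr_control,
    filtered_bh_control,
    meandiff_stat,
    min_achievable_pvalues,
    n_distinct_assignments,
    per_feature_transform,
    permutation_null,
    permutation_pvalues,
)


class TestTransformsAndStat:
    def test_midranks_for_ties(self):
        x = np.array([[5.0], [5.0], [1.0]])
        np.testing.assert_array_equal(per_feature_transform(x, "rank")[:, 0], [2.5, 2.5, 1.0])

    def test_rank_of_strictly_increasing_is_identity(self):
        x = np.arange(1, 7, dtype=float)[:, None]
        np.testing.assert_array_equal(per_feature_transform(x, "rank")[:, 0], np.arange(1, 7))

    def test_all_equal_feature_ranks_equal(self):
        x = np.full((5, 1), 3.0)
        assert len(set(per_feature_transform(x, "rank")[:, 0])) == 1

    def test_meandiff_forced_and_antisymmetric(self):
        x = np.array([[1.0], [1.0], [0.0], [0.0]])
        labels = np.array([True, True, False, False])
        assert meandiff_stat(x, labels)[0] == 1.0
        assert meandiff_stat(x, ~labels)[0] == -1.0

    def test_meandiff_requires_both_groups(self):
        with pytest.raises(ValidationError):
            meandiff_stat(np.ones((3, 1)), np.array([True, True, True]))


def _separated_fixture(n1=4, n2=4, n_features=20, seed=0):
    """Feature 0 perfectly separates the groups; the rest are noise."""
    rng = np.random.default_rng(seed)
    x = rng.poisson(5, size=(n1 + n2, n_features)).astype(float)
    x[:n1, 0] = [10.0, 11.0, 12.0, 13.0][:n1]
    x[n1:, 0] = 0.0
    labels = np.array([True] * n1 + [False] * n2)
    return x, labels


class TestPermutationNull:
    def test_exhaustive_enumerates_all_assignments(self):
        x, labels = _separated_fixture()
        S = permutation_null(x, labels, exhaustive=True)
        assert S.shape == (70, 20)
        assert n_distinct_assignments(8, 4) == 70

    def test_exhaustive_cap_suggests_random_mode(self):
        x = np.ones((30, 2))
        labels = np.array([True] * 15 + [False] * 15)
        with pytest.raises(ValidationError, match="random"):
            permutation_null(x, labels, exhaustive=True)

    def test_constant_feature_null_is_zero(self):
        x, labels = _separated_fixture()
        x[:, 5] = 7.0
        S = permutation_null(x, labels, exhaustive=True)
        np.testing.assert_array_equal(S[:, 5], 0.0)

    def test_random_mode_is_seeded(self):
        x, labels = _separated_fixture()
        a = permutation_null(x, labels, n_permutations=50, seed=9)
        b = permutation_null(x, labels, n_permutations=50, seed=9)
        np.testing.assert_array_equal(a, b)


class TestPermutationPvalues:
    def test_add_one_rule_floor(self):
        s_obs = np.array([100.0])
        S = np.zeros((999, 1))
        p = permutation_pvalues(s_obs, S)
        assert p[0] == pytest.approx(1 / 1000)

    def test_zero_stat_with_symmetric_null_gives_one(self):
        s_obs = np.array([0.0])
        S = np.array([[1.0], [-1.0], [0.5]])
        assert permutation_pvalues(s_obs, S)[0] == 1.0

    def test_perfect_separation_exhaustive_p_is_2_over_70(self):
        """Rank transform, 4+4 samples: only the true split and its mirror
        attain the extreme |mean rank difference|."""
        x, labels = _separated_fixture()
        xr = per_feature_transform(x[:, :1], "rank")
        s_obs = meandiff_stat(xr, labels)
        S = permutation_null(xr, labels, exhaustive=True)
        p = permutation_pvalues(s_obs, S, exhaustive=True)
        assert p[0] == pytest.approx(2 / 70)

    def test_monte_carlo_within_binomial_ci_of_exhaustive(self):
        """Independent oracle: exact enumeration over all 70 assignments."""
        import scipy.stats

        x, labels = _separated_fixture(seed=4)
        xr = per_feature_transform(x, "rank")
        s_obs = meandiff_stat(xr, labels)
        S_ex = permutation_null(xr, labels, exhaustive=True)
        p_ex = permutation_pvalues(s_obs, S_ex, exhaustive=True)
        B = 999
        S_mc = permutation_null(xr, labels, n_permutations=B, seed=12)
        counts = (np.abs(S_mc) >= np.abs(s_obs)[None, :]).sum(axis=0)
        lo, hi = scipy.stats.binom.interval(0.99, B, p_ex)
        assert np.all(counts >= lo) and np.all(counts <= hi)


def dsfdr_brute_force(s_obs, S_perm, alpha):
    """Independent O(F^2 B) threshold scan over every candidate threshold."""
    t_obs = np.abs(s_obs)
    A = np.abs(S_perm)
    best_t = None
    for t in sorted(t_obs):  # ascending: first qualifying is the smallest
        R = (t_obs >= t).sum()
        V = (A >= t).sum() / A.shape[0]
        if min(1.0, V / max(1, R)) <= alpha:
            best_t = t
            break
    if best_t is None:
        return np.zeros(t_obs.size, dtype=bool), None
    return t_obs >= best_t, best_t


class TestDsFDR:
    def test_null_equal_to_observed_rejects_nothing(self):
        s_obs = np.array([1.0, 2.0, 3.0])
        S = np.tile(s_obs, (50, 1))
        rejected, threshold, q = dsfdr_control(s_obs, S, alpha=0.1)
        assert not rejected.any()
        assert threshold is None
        np.testing.assert_array_equal(q, 1.0)

    def test_alpha_one_rejects_everything_with_cap(self):
        rng = np.random.default_rng(1)
        s_obs = rng.normal(size=30)
        S = rng.normal(size=(100, 30))
        rejected, threshold, q = dsfdr_control(s_obs, S, alpha=1.0)
        assert rejected.all()

    def test_rejected_implies_q_below_alpha(self):
        rng = np.random.default_rng(2)
        s_obs = np.r_[rng.normal(size=50), rng.normal(5, 1, size=10)]
        S = rng.normal(size=(200, 60))
        rejected, threshold, q = dsfdr_control(s_obs, S, alpha=0.1)
        assert np.all(q[rejected] <= 0.1)
        # q monotone non-increasing in |s|
        order = np.argsort(np.abs(s_obs))
        assert np.all(np.diff(q[order]) <= 1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_threshold_scan(self, seed):
        exp, truth = ax.make_count_experiment(
            n_per_group=(4, 4), n_features=30, n_diff=5, seed=seed
        )
        labels = exp.sample_metadata["group"].to_numpy() == "group1"
        x = per_feature_transform(exp.dense(), "rank")
        s_obs = meandiff_stat(x, labels)
        S = permutation_null(x, labels, exhaustive=True)
        rej, thr, _ = dsfdr_control(s_obs, S, alpha=0.1)
        rej_bf, thr_bf = dsfdr_brute_force(s_obs, S, alpha=0.1)
        np.testing.assert_array_equal(rej, rej_bf)
        assert thr == thr_bf

    def test_rejections_monotone_in_alpha(self):
        rng = np.random.default_rng(3)
        s_obs = np.r_[rng.normal(size=80), rng.normal(4, 1, size=20)]
        S = rng.normal(size=(300, 100))
        small, _, _ = dsfdr_control(s_obs, S, alpha=0.05)
        large, _, _ = dsfdr_control(s_obs, S, alpha=0.2)
        assert np.all(large[small])  # small-alpha set is a subset


class TestBH:
    def test_single_small_p_rejected(self):
        rejected, q = bh_control(np.array([0.04]), alpha=0.05)
        assert rejected[0] and q[0] == pytest.approx(0.04)

    def test_all_ones_give_no_rejections(self):
        rejected, q = bh_control(np.ones(10), alpha=0.1)
        assert not rejected.any()
        np.testing.assert_array_equal(q, 1.0)

    def test_agrees_with_naive_stepup_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        for _ in range(10):
            p = rng.random(40) ** 2
            rejected, q = bh_control(p, alpha=0.1)
            # naive O(m^2) step-up
            m = p.size
            order = np.argsort(p)
            k_max = 0
            for k in range(1, m + 1):
                if p[order[k - 1]] <= 0.1 * k / m:
                    k_max = k
            naive = np.zeros(m, dtype=bool)
            naive[order[:k_max]] = True
            np.testing.assert_array_equal(rejected, naive)
            sm_rej, sm_q, _, _ = multipletests(p, alpha=0.1, method="fdr_bh")
            np.testing.assert_array_equal(rejected, sm_rej)
            np.testing.assert_allclose(q, sm_q, atol=1e-12)


class TestFilteredBH:
    def test_reduces_to_bh_when_all_attainable(self):
        rng = np.random.default_rng(5)
        p = rng.random(30)
        p_min = np.full(30, 1e-4)
        a_rej, a_q = filtered_bh_control(p, p_min, alpha=0.1)
        b_rej, b_q = bh_control(p, alpha=0.1)
        np.testing.assert_array_equal(a_rej, b_rej)
        np.testing.assert_allclose(a_q, b_q)

    def test_single_presence_feature_excluded_from_family(self):
        """A feature present in 1 of 8 samples has a constant binarized
        exhaustive null, so its minimal achievable p is 1."""
        x = np.zeros((8, 1))
        x[0, 0] = 4.0
        labels = np.array([True] * 4 + [False] * 4)
        xb = per_feature_transform(x, "binarize")
        S = permutation_null(xb, labels, exhaustive=True)
        p_min = min_achievable_pvalues(S, exhaustive=True)
        assert p_min[0] == 1.0
        rejected, q = filtered_bh_control(np.array([0.5]), p_min, alpha=0.1)
        assert not rejected[0] and q[0] == 1.0

    def test_never_fewer_rejections_than_bh(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            p = rng.random(50) ** 3
            p_min = np.where(rng.random(50) < 0.4, 1.0, 1e-4)
            p = np.maximum(p, p_min)  # a p-value can never beat its support
            f_rej, _ = filtered_bh_control(p, p_min, alpha=0.1)
            b_rej, _ = bh_control(p, alpha=0.1)
            assert f_rej.sum() >= b_rej.sum()


class TestDiffAbundance:
    def _spec(self, **kw):
        base = dict(field="group", group1_values=["group1"], group2_values=["group2"], seed=0)
        base.update(kw)
        return TestSpec(**base)

    def test_constant_matrix_gives_no_rejections(self):
        exp, _ = ax.make_count_experiment(seed=0)
        exp = exp.copy(data=np.full(exp.shape, 3.0))
        res = ax.diff_abundance(exp, self._spec())
        np.testing.assert_array_equal(res.stat_obs, 0.0)
        assert not res.rejected.any()

    def test_planted_features_recovered(self):
        exp, truth = ax.make_count_experiment(seed=7)
        res = ax.diff_abundance(exp, self._spec(seed=7))
        assert res.rejected[truth].all()

    def test_presence_absence_pathway_direction(self):
        """A feature present only in group1 samples comes out direction=group1
        under the binarize transform."""
        exp, _ = ax.make_count_experiment(seed=1)
        data = exp.dense()
        data[:, 3] = 0.0
        data[:10, 3] = 50.0  # group1 samples only
        exp = exp.copy(data=data)
        res = ax.diff_abundance(exp, self._spec(transform="binarize"))
        assert res.direction[3] == "group1"
        assert res.rejected[3]

    def test_identical_spec_and_seed_bit_identical(self):
        exp, _ = ax.make_count_experiment(seed=2)
        r1 = ax.diff_abundance(exp, self._spec(seed=5))
        r2 = ax.diff_abundance(exp, self._spec(seed=5))
        np.testing.assert_array_equal(r1.stat_obs, r2.stat_obs)
        np.testing.assert_array_equal(r1.p_values, r2.p_values)
        np.testing.assert_array_equal(r1.q_values, r2.q_values)
        np.testing.assert_array_equal(r1.rejected, r2.rejected)

    def test_overlapping_groups_rejected(self):
        exp, _ = ax.make_count_experiment(seed=0)
        with pytest.raises(ValidationError, match="overlap"):
            ax.diff_abundance(
                exp, self._spec(group2_values=["group1", "group2"])
            )

    def test_group2_defaults_to_complement(self):
        exp, _ = ax.make_count_experiment(seed=3)
        a = ax.diff_abundance(exp, self._spec(group2_values=None))
        b = ax.diff_abundance(exp, self._spec())
        np.testing.assert_array_equal(a.stat_obs, b.stat_obs)


class TestCorrelation:
    def _monotone_exp(self, n=6, n_features=5):
        rng = np.random.default_rng(0)
        data = rng.poisson(10, (n, n_features)).astype(float)
        data[:, 0] = np.arange(1, n + 1) * 3.0  # strictly monotone in the field
        data[:, 1] = 5.0  # constant
        smd = pd.DataFrame(
            {"age": np.arange(n, dtype=float)},
            index=pd.Index([f"s{i}" for i in range(n)], name="sid"),
        )
        fmd = pd.DataFrame(index=pd.Index([f"f{j}" for j in range(n_features)], name="fid"))
        return ax.Experiment(data, smd, fmd)

    def test_constant_feature_stat_zero_p_one(self):
        res = ax.correlation_test(self._monotone_exp(), "age", n_permutations=200)
        assert res.stat_obs[1] == 0.0
        assert res.p_values[1] == 1.0

    def test_monotone_feature_exhaustive_p_2_over_720(self):
        res = ax.correlation_test(self._monotone_exp(), "age", method="spearman", exhaustive=True)
        assert res.p_values[0] == pytest.approx(2 / 720)

    def test_negating_field_negates_pearson_stats(self):
        exp = self._monotone_exp()
        res1 = ax.correlation_test(exp, "age", method="pearson", n_permutations=100)
        smd = exp.sample_metadata.copy()
        smd["age"] = -smd["age"]
        res2 = ax.correlation_test(exp.copy(sample_metadata=smd), "age",
                                   method="pearson", n_permutations=100)
        np.testing.assert_allclose(res1.stat_obs, -res2.stat_obs, atol=1e-12)

    def test_non_numeric_field_rejected(self, pond_exp):
        with pytest.raises(ValidationError):
            ax.correlation_test(pond_exp, "origin")

    def test_generator_covariate_detects_first_feature(self):
        exp, _ = ax.make_count_experiment(seed=9)
        res = ax.correlation_test(exp, "covariate", n_permutations=500, seed=1)
        assert res.rejected[0]


def test_type_one_error_under_global_null():
    """No planted effect: realized false-discovery proportion stays near the
    nominal level for all three correction methods (small-scale version of
    the full calibration in the acceptance suite)."""
    from abundex.stats import _stat_over_labelings

    n_fix = 30
    fdp = {"dsfdr": [], "bh": [], "filtered_bh": []}
    for s in range(n_fix):
        exp, _ = ax.make_count_experiment(effect_fold=1.0, n_diff=0, seed=300 + s)
        labels = exp.sample_metadata["group"].to_numpy() == "group1"
        x = per_feature_transform(exp.dense(), "rank")
        s_obs = _stat_over_labelings(x, labels[None, :], "meandiff")[0]
        S = permutation_null(x, labels, n_permutations=500, seed=s)
        p = permutation_pvalues(s_obs, S)
        rej_ds, _, _ = dsfdr_control(s_obs, S, alpha=0.1)
        rej_bh, _ = bh_control(p, alpha=0.1)
        rej_f, _ = filtered_bh_control(p, min_achievable_pvalues(S), alpha=0.1)
        for name, rej in [("dsfdr", rej_ds), ("bh", rej_bh), ("filtered_bh", rej_f)]:
            fdp[name].append(1.0 if rej.any() else 0.0)
    se = np.sqrt(0.1 * 0.9 / n_fix)
    for name, vals in fdp.items():
        assert np.mean(vals) <= 0.1 + 3 * se, f"{name}: {np.mean(vals)}"
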