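import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctcount import (euclidean_dm, generate_flower_table, grouping_letters,
                     mww_exact, ols_f, permanova, permanova_posthoc,
                     table1_summary, weighted_strategy_means)


def brute_force_mww(x, y):
    """Complete enumeration of the two-sample permutation null of U.

    Independent oracle: every C(n1+n2, n1) assignment of the pooled
    values to group 1 is enumerated directly.
    """
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj) \
        + 0.5 * sum(1 for xi in x for yj in y if xi == yj)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        g1 = pooled[list(idx)]
        g2 = np.delete(pooled, list(idx))
        us.append(sum(1 for a in g1 for b in g2 if a > b)
                  + 0.5 * sum(1 for a in g1 for b in g2 if a == b))
    us = np.array(us)
    lower = (us <= u_obs).mean()
    upper = (us >= u_obs).mean()
    return u_obs, min(1.0, 2.0 * min(lower, upper))


class TestEuclideanDM:
    def test_scalar_absolute_differences(self):
        d = euclidean_dm([0.0, 3.0, 4.0])
        np.testing.assert_allclose(d, [[0, 3, 4], [3, 0, 1], [4, 1, 0]])

    def test_identical_samples_zero_matrix(self):
        assert not euclidean_dm([5.0, 5.0, 5.0]).any()

    def test_two_component_vectors_match_hand_formula(self):
        d = euclidean_dm([[0.0, 0.0], [3.0, 4.0]])
        assert d[0, 1] == pytest.approx(5.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            euclidean_dm([1.0, np.nan])


class TestPermanova:
    def test_pseudo_f_equals_classical_anova_f(self, rng):
        """Oracle identity on 100 random univariate datasets."""
        for _ in range(100):
            sizes = rng.integers(3, 8, size=3)
            g = np.repeat(list("abc"), sizes)
            y = rng.normal(size=len(g)) + rng.normal() * (g == "b")
            res = permanova(euclidean_dm(y), pd.DataFrame({"g": g}), ["g"],
                            n_perm=9, seed=0)
            groups = [y[g == lv] for lv in "abc"]
            f_classical = stats.f_oneway(*groups).statistic
            assert res.table.loc["g", "F"] == pytest.approx(f_classical, abs=1e-9)

    def test_identical_observations_flagged_undefined(self):
        d = euclidean_dm([2.0] * 6)
        res = permanova(d, pd.DataFrame({"g": list("aabbcc")}), n_perm=9, seed=0)
        assert res.undefined

    def test_r_squared_partition_sums_to_one(self, rng):
        tbl = generate_flower_table(seed=2)
        d = euclidean_dm(tbl["ovules"].to_numpy())
        res = permanova(d, tbl, ["species", "position", "species:position"],
                        n_perm=49, seed=1)
        terms_r2 = res.table["R2"].iloc[:-2].sum()
        assert terms_r2 + res.table.loc["Residual", "R2"] == pytest.approx(1.0)

    def test_p_value_bounds_and_reproducibility(self, rng):
        y = rng.normal(size=12)
        d = euclidean_dm(y)
        design = pd.DataFrame({"g": list("ab") * 6})
        r1 = permanova(d, design, n_perm=99, seed=7)
        r2 = permanova(d, design, n_perm=99, seed=7)
        assert r1.table.loc["g", "p"] == r2.table.loc["g", "p"]
        assert r1.table.loc["g", "p"] >= 1 / 100

    def test_strong_effect_detected(self):
        # perfectly separated groups: only label-preserving permutations
        # (probability 2/C(16,8)) can match the observed F
        y = np.r_[np.zeros(8), np.ones(8) * 10]
        d = euclidean_dm(y)
        res = permanova(d, pd.DataFrame({"g": ["a"] * 8 + ["b"] * 8}),
                        n_perm=999, seed=3)
        assert res.table.loc["g", "p"] <= 3 / 1000

    def test_unknown_factor_rejected(self, rng):
        d = euclidean_dm(rng.normal(size=6))
        with pytest.raises(ValueError):
            permanova(d, pd.DataFrame({"g": list("aabbcc")}), ["h"], n_perm=9)


class TestPosthoc:
    def test_bonferroni_arithmetic_three_levels(self, rng):
        y = np.r_[rng.normal(0, 1, 6), rng.normal(5, 1, 6), rng.normal(10, 1, 6)]
        f = np.repeat(list("abc"), 6)
        ph = permanova_posthoc(euclidean_dm(y), f, n_perm=99, seed=5)
        assert len(ph) == 3
        np.testing.assert_allclose(ph["p_adj"], np.minimum(1.0, ph["p"] * 3))

    def test_identical_levels_rarely_significant(self, rng):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            y = r.normal(size=18)
            f = np.repeat(list("abc"), 6)
            ph = permanova_posthoc(euclidean_dm(y), f, n_perm=99, seed=seed)
            hits += (ph["p_adj"] <= 0.05).any()
        assert hits <= 2  # ~95% of seeds show no significant pair

    def test_grouping_letters_deterministic(self):
        ph = pd.DataFrame({
            "level_a": ["a", "a", "b"], "level_b": ["b", "c", "c"],
            "p": [0.9, 0.001, 0.001], "p_adj": [1.0, 0.003, 0.003],
        })
        letters = grouping_letters(ph)
        assert letters == grouping_letters(ph)
        assert set(letters["a"]) & set(letters["b"])  # a,b share a letter
        assert not set(letters["a"]) & set(letters["c"])


class TestMWWExact:
    def test_published_variance_comparison_w_zero(self):
        """Per-species P:O variances, rewarding vs deceptive -> W = 0."""
        res = mww_exact([152, 147, 175], [49, 22, 23, 46, 30])
        assert res.w == 0.0 and res.n1 == 3 and res.n2 == 5
        assert res.method == "exact"
        assert res.p == pytest.approx(2 / 56)  # prints as 0.035 at 2 decimals
        assert round(res.p, 2) == 0.04 or round(res.p, 3) == 0.036

    def test_identical_samples_p_one(self):
        res = mww_exact([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p == 1.0

    @pytest.mark.parametrize("n1,n2", [(1, 1), (2, 3), (3, 5), (4, 4), (5, 5), (2, 8)])
    def test_exact_p_matches_complete_enumeration(self, n1, n2, rng):
        """All tie-free samples with n1 + n2 <= 10 against the brute-force oracle."""
        for _ in range(5):
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            x, y = pooled[:n1], pooled[n1:]
            res = mww_exact(x, y)
            u_obs, p_oracle = brute_force_mww(x, y)
            assert res.p == pytest.approx(p_oracle, abs=1e-12)
            assert res.w == min(u_obs, n1 * n2 - u_obs)

    def test_agrees_with_scipy_exact(self, rng):
        for _ in range(20):
            x = rng.normal(size=4)
            y = rng.normal(size=6)
            res = mww_exact(x, y)
            sp = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert res.p == pytest.approx(sp.pvalue, abs=1e-12)
            assert res.w in (sp.statistic, len(x) * len(y) - sp.statistic)

    def test_ties_fall_back_to_normal_approximation(self):
        res = mww_exact([1, 1, 2], [2, 3, 3])
        assert res.method == "normal"
        assert 0 < res.p <= 1

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mww_exact([], [1.0])


class TestOlsF:
    def test_perfect_collinearity(self):
        F, df1, df2, p, r2 = ols_f([1, 2, 3, 4], [2, 4, 6, 8])
        assert math.isinf(F) and r2 == 1.0 and p == 0.0

    def test_hand_computed_four_points(self):
        # x = 0,1,2,3 ; y = 1,2,2,4 -> slope 0.9, SS_reg = 4.05, SS_res = 0.7
        x, y = np.array([0, 1, 2, 3.0]), np.array([1, 2, 2, 4.0])
        F, df1, df2, p, r2 = ols_f(x, y)
        assert (df1, df2) == (1, 2)
        assert F == pytest.approx(4.05 / (0.7 / 2))
        assert r2 == pytest.approx(4.05 / 4.75)

    def test_matches_scipy_linregress(self, rng):
        x = rng.normal(size=12)
        y = 0.5 * x + rng.normal(size=12)
        F, _, _, p, r2 = ols_f(x, y)
        lr = stats.linregress(x, y)
        assert p == pytest.approx(lr.pvalue, rel=1e-9)
        assert r2 == pytest.approx(lr.rvalue ** 2, rel=1e-9)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            ols_f([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestTable1Summary:
    def test_per_species_se_is_sd_over_sqrt_n(self):
        tbl = generate_flower_table(seed=4)
        summ = table1_summary(tbl)
        sp = tbl[tbl.species == tbl.species.iloc[0]]
        row = summ.species.loc[tbl.species.iloc[0]]
        assert row["pollen_se"] == pytest.approx(
            sp["pollen"].std(ddof=1) / math.sqrt(len(sp)))
        assert row["pollen_n"] == len(sp)

    def test_row_order_invariance(self):
        tbl = generate_flower_table(seed=4)
        shuffled = tbl.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = table1_summary(tbl)
        b = table1_summary(shuffled)
        pd.testing.assert_frame_equal(a.species, b.species)
        assert a.po_variance_ratio == pytest.approx(b.po_variance_ratio)

    def test_single_species_weighted_mean_equals_species_mean(self):
        tbl = generate_flower_table(seed=4)
        one = tbl[tbl.species == tbl.species.iloc[0]]
        summ = table1_summary(one)
        strat = one.strategy.iloc[0]
        assert summ.strategy.loc[strat, "ovules_weighted_mean"] == pytest.approx(
            one["ovules"].mean())

    def test_missing_strategy_rejected(self):
        tbl = generate_flower_table(seed=4)
        tbl.loc[0, "strategy"] = np.nan
        with pytest.raises(ValueError):
            table1_summary(tbl)


class TestWeightedStrategyMeans:
    def test_published_group_means_from_species_summaries(self):
        """N-weighted ovule means over the printed per-species table."""
        from ctcount.data import species_summary
        df = species_summary()
        means = weighted_strategy_means(df, "ovule_mean", "ovule_n")
        assert round(means["deceptive"]) == 6408
        assert round(means["rewarding"]) == 2342
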