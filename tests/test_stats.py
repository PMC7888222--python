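"""Tests for rhythm statistics: Friedman/Dunn, randomization null,
correlations and between-group tests, each against an independent oracle."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats as sps

from conftest import child_seeds, make_pattern
from neurorhythm import simulate, traces
from neurorhythm.stats import (
    anova2_tukey,
    anova_dunnett,
    dunn_posthoc,
    friedman_test,
    kruskal_dunn,
    mann_whitney,
    pattern_correlation,
    randomization_null,
    split_half_correlation,
)
from neurorhythm.stats import _friedman_statistic, _kruskal_h


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the package's DP implementations)


def brute_friedman_p(x):
    ranks = sps.rankdata(x, axis=1)
    n, k = x.shape
    tie_term = sum(
        float(np.sum(c**3 - c)) for c in (np.unique(row, return_counts=True)[1] for row in x)
    )
    obs = _friedman_statistic(ranks.sum(axis=0), n, k, tie_term)
    hits = total = 0
    for perms in itertools.product(*[list(itertools.permutations(r)) for r in ranks]):
        s = _friedman_statistic(np.sum(perms, axis=0), n, k, tie_term)
        total += 1
        hits += s >= obs - 1e-9
    return obs, hits / total


def brute_kruskal_p(groups):
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    n = pooled.size
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0] + sizes)
    obs = _kruskal_h([ranks[bounds[i] : bounds[i + 1]] for i in range(len(groups))], n, tie_term)
    hits = total = 0
    for assign in itertools.permutations(range(n)):
        gr = [np.array([ranks[assign[i]] for i in range(bounds[j], bounds[j + 1])]) for j in range(len(groups))]
        h = _kruskal_h(gr, n, tie_term)
        total += 1
        hits += h >= obs - 1e-9
    return obs, hits / total


# ---------------------------------------------------------------------------
# Friedman


class TestFriedman:
    def test_all_tied_gives_zero_statistic(self):
        x = np.tile([3.0, 3.0, 3.0], (5, 1))
        res = friedman_test(x)
        assert res.statistic == 0.0 and res.p_value == 1.0

    @pytest.mark.parametrize("shape,seed", [((4, 3), 0), ((5, 3), 1), ((4, 4), 2)])
    def test_exact_p_matches_enumeration_oracle(self, shape, seed):
        x = np.random.default_rng(seed).normal(size=shape)
        res = friedman_test(x, method="exact")
        obs, p = brute_friedman_p(x)
        assert res.statistic == pytest.approx(obs)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_monotone_rows_reach_minimal_p(self):
        x = np.cumsum(np.ones((5, 3)), axis=1) + np.arange(5)[:, None]
        res = friedman_test(x, method="exact")
        obs, p = brute_friedman_p(x)
        assert res.p_value == pytest.approx(p)
        assert res.p_value == pytest.approx(6 / 6**5)  # only fully aligned orderings

    def test_chi2_statistic_matches_scipy(self, small_culture):
        *_, pattern = small_culture
        res = friedman_test(pattern, method="chi2")
        ref = sps.friedmanchisquare(*pattern.scores.T)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_incomplete_matrix_rejected(self):
        x = np.ones((4, 3))
        x[1, 2] = np.nan
        with pytest.raises(ValueError):
            friedman_test(x)


class TestDunnPosthoc:
    def test_all_tied_adjusted_p_is_one(self):
        comps = dunn_posthoc(np.tile([2.0, 2.0, 2.0], (6, 1)))
        assert all(c.adjusted_p == 1.0 for c in comps)

    def test_two_conditions_family_of_one(self):
        x = np.random.default_rng(5).normal(size=(8, 2))
        (comp,) = dunn_posthoc(x)
        assert comp.adjusted_p == pytest.approx(comp.p_value)

    def test_z_matches_hand_formula(self):
        x = np.array([[1.0, 2.0, 3.0], [2.0, 1.0, 3.0], [1.0, 3.0, 2.0], [1.0, 2.0, 3.0]])
        comps = dunn_posthoc(x, reference_index=0)
        ranks = sps.rankdata(x, axis=1)
        n, k = x.shape
        se = math.sqrt(k * (k + 1) / (6 * n))  # no ties in any row
        for c in comps:
            z_hand = (ranks[:, c.condition_index].mean() - ranks[:, 0].mean()) / se
            assert c.z == pytest.approx(z_hand)
            assert c.p_value == pytest.approx(2 * sps.norm.sf(abs(z_hand)))
            assert c.adjusted_p >= c.p_value

    def test_reference_out_of_range(self):
        with pytest.raises(ValueError):
            dunn_posthoc(np.ones((4, 3)), reference_index=3)


class TestRandomizationNull:
    def test_same_seed_bitwise_identical(self, small_culture):
        *_, pattern = small_culture
        r1 = randomization_null(pattern, n_reps=200, seed=11)
        r2 = randomization_null(pattern, n_reps=200, seed=11)
        assert np.array_equal(r1.raw_p, r2.raw_p)
        assert np.array_equal(r1.adjusted_p, r2.adjusted_p)

    def test_type_one_error_calibrated_on_exchangeable_null(self):
        """i.i.d. rows: ~5% of permuted Friedman p fall below 0.05 and no
        Bonferroni-adjusted p is significant."""
        rng = np.random.default_rng(21)
        pattern = make_pattern(rng.normal(size=(80, 9)))
        res = randomization_null(pattern, n_reps=1000, seed=22)
        assert 0.03 <= res.fraction_raw_significant <= 0.07
        assert res.fraction_adjusted_significant == 0.0

    def test_rhythmic_pattern_beats_every_permutation(self):
        cfg = simulate.CultureSimConfig(
            n_neurons=100, session_times_h=tuple(range(0, 36, 4)), seed=33
        )
        recs, _ = simulate.simulate_culture(cfg)
        pattern = traces.assemble_pattern(traces.score_recordings(recs))
        res = randomization_null(pattern, n_reps=1000, seed=34)
        assert res.observed.p_value < res.raw_p.min()

    def test_single_rep_is_a_friedman_test_of_a_permuted_matrix(self):
        """Shuffling scores within rows then testing equals the fast path."""
        rng = np.random.default_rng(44)
        x = rng.normal(size=(15, 6))
        xp = np.array([rng.permutation(row) for row in x])
        direct = friedman_test(xp, method="chi2")
        # any within-row permutation leaves the null machinery invariant, so a
        # 1-rep null of xp must draw its p from the same distribution support
        res = randomization_null(make_pattern(xp), n_reps=500, seed=45)
        assert direct.p_value >= res.raw_p.min() - 1e-12
        assert np.all((res.raw_p >= 0) & (res.raw_p <= 1))

    def test_adjusted_at_least_raw(self, small_culture):
        *_, pattern = small_culture
        res = randomization_null(pattern, n_reps=100, seed=5)
        assert np.all(res.adjusted_p >= res.raw_p)

    def test_invalid_reps(self, small_culture):
        *_, pattern = small_culture
        with pytest.raises(ValueError):
            randomization_null(pattern, n_reps=0)


# ---------------------------------------------------------------------------
# correlations


class TestCorrelations:
    def test_perfect_and_antiperfect(self):
        x = np.array([1.0, 2.0, 4.0, 7.0, 8.0])
        assert pattern_correlation(x, x).r == pytest.approx(1.0)
        assert pattern_correlation(x, -2 * x + 7).r == pytest.approx(-1.0)

    def test_affine_sign_property(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=9)
        for b in (0.5, -3.0):
            assert pattern_correlation(x, 2 + b * x).r == pytest.approx(math.copysign(1, b))

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=9), rng.normal(size=9)
        res = pattern_correlation(x, y)
        r_hand = np.sum((x - x.mean()) * (y - y.mean())) / math.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        t = r_hand * math.sqrt(7 / (1 - r_hand**2))
        assert res.r == pytest.approx(r_hand)
        assert res.p_value == pytest.approx(2 * sps.t.sf(abs(t), 7))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pattern_correlation(np.ones(5), np.arange(5.0))

    def test_split_half_periodic_pattern(self):
        t = np.arange(0, 64, 4.0)
        mean_curve = 1 + 0.5 * np.sin(2 * np.pi * t / 32.0)  # period == window
        pat = make_pattern(np.tile(mean_curve, (3, 1)) * [[1.0], [2.0], [0.5]], t)
        assert split_half_correlation(pat, window_h=32).r == pytest.approx(1.0)

    def test_split_half_null_halves_weakly_correlated(self):
        rng = np.random.default_rng(31)
        rs = []
        t = np.arange(0, 64, 4.0)
        for _ in range(100):
            pat = make_pattern(rng.normal(10, 1, size=(5, 16)), t)
            rs.append(abs(split_half_correlation(pat, window_h=32).r))
        assert np.mean(rs) < 0.35

    def test_split_half_span_too_short(self):
        pat = make_pattern(np.random.default_rng(1).normal(size=(3, 10)), np.arange(0, 40, 4.0))
        with pytest.raises(ValueError):
            split_half_correlation(pat, window_h=32)


# ---------------------------------------------------------------------------
# between-group tests


class TestMannWhitney:
    def test_identical_samples_near_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = mann_whitney(a, a.copy())
        assert res.p_value > 0.9
        assert res.statistic == pytest.approx(8.0)  # U at its null mean

    def test_exact_small_sample_oracle(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.extra["method"] == "exact"
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2/20 labelings as extreme

    def test_exact_matches_full_enumeration(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=5), rng.normal(size=4)
        res = mann_whitney(a, b)
        pooled = np.concatenate([a, b])
        u_obs = res.statistic
        us = []
        for idx in itertools.combinations(range(9), 5):
            aa = pooled[list(idx)]
            bb = pooled[[i for i in range(9) if i not in idx]]
            us.append(sum((x > y) + 0.5 * (x == y) for x in aa for y in bb))
        us = np.array(us)
        mu = len(a) * len(b) / 2
        p_brute = np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-9)
        assert res.p_value == pytest.approx(p_brute, abs=1e-12)

    def test_power_on_shifted_normals(self):
        rng = np.random.default_rng(17)
        rejections = sum(
            mann_whitney(rng.normal(0, 1, 20), rng.normal(2, 1, 20)).p_value < 0.05
            for _ in range(500)
        )
        assert rejections / 500 > 0.9

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestKruskalDunn:
    def test_identical_constants(self):
        res = kruskal_dunn([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
        assert res.statistic == 0.0 and res.p_value == 1.0
        assert all(c.adjusted_p == 1.0 for c in res.comparisons)

    def test_exact_matches_enumeration_oracle(self):
        groups = [np.array([1.2, 3.4, 2.2]), np.array([5.1, 4.4]), np.array([0.5, 2.9])]
        res = kruskal_dunn(groups, method="exact")
        obs, p = brute_kruskal_p(groups)
        assert res.statistic == pytest.approx(obs)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_two_groups_consistent_with_rank_test(self):
        """For 2 groups the tie-corrected H equals the squared normal deviate
        of the Mann-Whitney z (chi-square vs normal convention)."""
        rng = np.random.default_rng(23)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)
        res_k = kruskal_dunn([a, b], method="chi2")
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                               use_continuity=False)
        z = sps.norm.isf(ref.pvalue / 2)
        assert res_k.statistic == pytest.approx(z**2, rel=1e-6)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(29)
        res = kruskal_dunn([rng.normal(size=9) for _ in range(4)], method="chi2")
        for c in res.comparisons:
            assert c.adjusted_p >= c.p_value


class TestAnovaDunnett:
    def test_two_groups_reduce_to_t_test(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 12), rng.normal(0.7, 1, 12)
        res = anova_dunnett([a, b], seed=0)
        t_p = sps.ttest_ind(b, a).pvalue
        assert res.comparisons[0].adjusted_p == pytest.approx(t_p, abs=0.002)

    def test_f_matches_sum_of_squares_oracle(self):
        groups = [np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 4.5]), np.array([6.0, 7.0, 5.5])]
        res = anova_dunnett(groups, seed=0)
        allv = np.concatenate(groups)
        ssb = sum(len(g) * (g.mean() - allv.mean()) ** 2 for g in groups)
        ssw = sum(np.sum((g - g.mean()) ** 2) for g in groups)
        f_hand = (ssb / 2) / (ssw / 6)
        assert res.statistic == pytest.approx(f_hand)

    def test_family_type_one_error_controlled(self):
        """Null 3-group design: the Dunnett family rejects at <= alpha + margin."""
        rng = np.random.default_rng(19)
        fam_rej = 0
        n_sims = 400
        for _ in range(n_sims):
            groups = [rng.normal(0, 1, 8) for _ in range(3)]
            res = anova_dunnett(groups, seed=int(rng.integers(2**31)))
            fam_rej += any(c.adjusted_p < 0.05 for c in res.comparisons)
        assert fam_rej / n_sims <= 0.05 + 0.025  # binomial slack at 400 sims

    def test_degenerate_variance_handled(self):
        res = anova_dunnett([[1.0, 1.0], [2.0, 2.0]])
        assert res.p_value == 0.0
        assert res.comparisons[0].significant


class TestAnova2Tukey:
    @staticmethod
    def table(rng, effect_a=0.0, effect_b=0.0, interaction=0.0, reps=6):
        import pandas as pd

        rows = []
        for la in ("x", "y"):
            for lb in ("u", "v"):
                mu = (
                    effect_a * (la == "y")
                    + effect_b * (lb == "v")
                    + interaction * ((la == "y") and (lb == "v"))
                )
                for _ in range(reps):
                    rows.append({"value": rng.normal(mu, 1), "factor_a": la, "factor_b": lb})
        return pd.DataFrame(rows)

    def test_type_one_error_near_alpha(self):
        rng = np.random.default_rng(37)
        rej = {"a": 0, "b": 0, "ab": 0}
        n_sims = 300
        for _ in range(n_sims):
            res = anova2_tukey(self.table(rng))
            rej["a"] += res.extra["p_factor_a"] < 0.05
            rej["b"] += res.extra["p_factor_b"] < 0.05
            rej["ab"] += res.extra["p_interaction"] < 0.05
        for key, count in rej.items():
            assert 0.01 <= count / n_sims <= 0.10, key  # ~alpha with binomial slack

    def test_large_main_effect_detected(self):
        rng = np.random.default_rng(41)
        res = anova2_tukey(self.table(rng, effect_a=3.0, reps=8))
        assert res.extra["p_factor_a"] < 0.001
        assert res.extra["p_factor_b"] > 0.05
        assert res.extra["p_interaction"] > 0.05

    def test_tukey_p_values_match_scipy_over_cells(self):
        rng = np.random.default_rng(43)
        df = self.table(rng, effect_a=1.0)
        res = anova2_tukey(df)
        cells = [
            df.loc[(df.factor_a == a) & (df.factor_b == b), "value"].to_numpy()
            for a in ("x", "y")
            for b in ("u", "v")
        ]
        ref = sps.tukey_hsd(*cells)
        got = {c.label: c.adjusted_p for c in res.comparisons}
        assert got["y:v vs x:u"] == pytest.approx(float(ref.pvalue[0, 3]))

    def test_single_replicate_per_cell_rejected(self):
        rng = np.random.default_rng(47)
        with pytest.raises(ValueError, match="residual"):
            anova2_tukey(self.table(rng, reps=1))

    def test_empty_cell_named(self):
        rng = np.random.default_rng(53)
        df = self.table(rng)
        df = df[~((df.factor_a == "y") & (df.factor_b == "v"))]
        with pytest.raises(ValueError, match=r"\(y, v\)"):
            anova2_tukey(df)
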