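"""Summary grids, nonparametric tests, zero-intercept regression, Chow test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from motophys import (GroupSpec, compare_slopes, fisher_exact, ks_test,
                      mann_whitney, sample_population, summarize,
                      zero_intercept_fit)
from motophys.errors import ValidationError


def mw_exact_oracle(a, b):
    """Two-tailed exact Mann-Whitney p by full enumeration of partitions."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    u_obs = sum(1 for x in a for y in b if x > y) + 0.5 * sum(
        1 for x in a for y in b if x == y)
    n_ab = len(a) * len(b)
    stat_obs = min(u_obs, n_ab - u_obs)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n_a):
        mask = np.zeros(len(pooled), bool)
        mask[list(comb)] = True
        u = sum(1 for x in pooled[mask] for y in pooled[~mask] if x > y)
        total += 1
        if min(u, n_ab - u) <= stat_obs + 1e-12:
            count += 1
    return count / total


def fisher_oracle(k11, k12, k21, k22):
    """Probability-mass two-tailed Fisher p via hypergeometric enumeration."""
    from scipy.stats import hypergeom
    n1, n2 = k11 + k12, k21 + k22
    c1 = k11 + k21
    rv = hypergeom(n1 + n2, n1, c1)
    support = np.arange(max(0, c1 - n2), min(c1, n1) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(k11)
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())


class TestSummarize:
    def test_single_row_group_degenerate(self):
        df = pd.DataFrame({"genotype": ["WT"], "rheobase": [0.5]})
        out = summarize(df, "genotype")
        assert out[("rheobase", "mean")].iloc[0] == 0.5
        assert out[("rheobase", "sd")].iloc[0] == 0.0
        assert out[("rheobase", "min")].iloc[0] == out[("rheobase", "max")].iloc[0]

    def test_missing_values_reduce_n(self):
        df = pd.DataFrame({"genotype": ["WT"] * 3, "x": [1.0, np.nan, 3.0]})
        out = summarize(df, "genotype")
        assert out[("x", "n")].iloc[0] == 2

    def test_population_rheobase_row_recovered(self):
        spec = GroupSpec.from_tables("WT", "immediate")
        cells = sample_population(spec, 1000, seed=1)
        df = pd.DataFrame({"genotype": ["WT"] * len(cells),
                           "rheobase": [c.rheobase_true for c in cells]})
        mean = summarize(df, "genotype")[("rheobase", "mean")].iloc[0]
        assert abs(mean - 0.6) <= 0.4 / math.sqrt(1000) + 0.01

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            summarize(pd.DataFrame({"genotype": [], "x": []}), "genotype")


class TestMannWhitney:
    def test_identical_samples(self):
        assert mann_whitney([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_exact_against_enumeration(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        assert mann_whitney(a, b) == pytest.approx(mw_exact_oracle(a, b))
        assert mann_whitney(a, b) == pytest.approx(0.1)  # 2 of 20 partitions

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_exact_matches_oracle_random_small_samples(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, rng.integers(2, 6))
        b = rng.normal(0.5, 1, rng.integers(2, 6))
        assert mann_whitney(a, b) == pytest.approx(mw_exact_oracle(a, b))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 15), rng.normal(1, 1, 12)
        assert mann_whitney(a, b) == pytest.approx(
            mann_whitney(np.exp(a), np.exp(b)))

    def test_power_on_table_rheobase_rows(self):
        """WT vs mSOD1 immediate rheobase (printed p = 0.008): the printed
        group distributions at the printed N reject at alpha=0.05 in well
        over half of replicate draws."""
        from motophys.sampling import matched_truncnorm
        wt = matched_truncnorm(0.6, 0.4, 0.05, 1.6)
        ms = matched_truncnorm(0.3, 0.2, 0.1, 0.6)
        rng = np.random.default_rng(11)
        rejections = sum(
            mann_whitney(wt.rvs(29, rng), ms.rvs(16, rng)) < 0.05
            for _ in range(100))
        assert rejections > 50

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])


class TestFisherExact:
    def test_mmo_proportion_table(self):
        # WT 13/15 vs mSOD1 3/11 immediate-firing cells with MMOs
        assert fisher_exact(13, 2, 3, 8) == pytest.approx(0.003, abs=0.0015)

    def test_balanced_table_is_one(self):
        assert fisher_exact(5, 5, 5, 5) == pytest.approx(1.0)

    def test_pattern_proportion_table_recomputed(self):
        # delayed/immediate proportions 63:31 vs 31:18; the exact two-tailed
        # probability-mass p recomputes to 0.71
        assert fisher_exact(63, 31, 31, 18) == pytest.approx(0.712, abs=0.005)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 8), st.integers(0, 8), st.integers(0, 8), st.integers(0, 8))
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if min(a + b, c + d, a + c, b + d) == 0:
            with pytest.raises(ValidationError):
                fisher_exact(a, b, c, d)
            return
        assert fisher_exact(a, b, c, d) == pytest.approx(
            fisher_oracle(a, b, c, d), rel=1e-9)


class TestKsTest:
    def test_identical_samples(self):
        x = np.arange(10.0)
        assert ks_test(x, x) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        from scipy.stats import ks_2samp
        a, b = np.arange(50.0), np.arange(100.0, 150.0)
        assert ks_2samp(a, b).statistic == 1.0
        assert ks_test(a, b) < 1e-20

    def test_dendritic_path_pools_differ(self):
        """WT vs mSOD1 immediate dendritic-path pools (printed N = 281/180)
        separate at p < 0.0001 in >= 95% of replicate draws."""
        from motophys.sampling import matched_truncnorm
        wt = matched_truncnorm(252, 141, 11, 803)
        ms = matched_truncnorm(181, 157, 11, 685)
        rng = np.random.default_rng(3)
        hits = sum(ks_test(wt.rvs(281, rng), ms.rvs(180, rng)) < 1e-4
                   for _ in range(40))
        assert hits >= 38


class TestZeroInterceptFit:
    def test_exact_line(self):
        G = np.array([10.0, 30.0, 50.0, 80.0])
        res = zero_intercept_fit(G, 0.022 * G)
        assert res.slope_mV == pytest.approx(22.0)
        np.testing.assert_allclose(res.residuals, 0.0, atol=1e-12)

    def test_single_point_ratio(self):
        res = zero_intercept_fit([50.0], [1.1])
        assert res.slope_mV == pytest.approx(22.0)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(7)
        G = rng.uniform(5, 100, 200)
        I = 0.02 * G + rng.normal(0, 0.1, 200)
        res = zero_intercept_fit(G, I)
        grid = np.linspace(res.slope_mV / 1000 - 0.005,
                           res.slope_mV / 1000 + 0.005, 20001)
        sse = ((I[:, None] - grid[None, :] * G[:, None]) ** 2).sum(axis=0)
        assert abs(grid[np.argmin(sse)] - res.slope_mV / 1000) <= 1e-6

    def test_u_equals_conductance_weighted_delta_v(self):
        """U is exactly the G^2-weighted mean of per-cell delta_V."""
        rng = np.random.default_rng(1)
        G = rng.uniform(5, 100, 50)
        dv = rng.uniform(10, 30, 50)      # heterogeneous thresholds, mV
        I = G * dv / 1000.0
        res = zero_intercept_fit(G, I)
        assert res.slope_mV == pytest.approx(np.sum(G**2 * dv) / np.sum(G**2))
        # homogeneous case: U equals that common delta_V exactly
        res2 = zero_intercept_fit(G, G * 0.020)
        assert res2.slope_mV == pytest.approx(20.0)

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValidationError):
            zero_intercept_fit([0.0, 0.0], [1.0, 2.0])


class TestCompareSlopes:
    def _group(self, rng, n, slope_mV, resid_sd=0.15):
        G = rng.uniform(6, 98, n)
        I = G * slope_mV / 1000.0 + rng.normal(0, resid_sd, n)
        return G, I

    def test_identical_groups(self):
        rng = np.random.default_rng(0)
        G, I = self._group(rng, 20, 22.0)
        cmp = compare_slopes(G, I, G, I)
        assert cmp.chow_F == pytest.approx(0.0, abs=1e-9)
        assert cmp.chow_pvalue == pytest.approx(1.0)
        assert cmp.t_stat == pytest.approx(0.0, abs=1e-9)

    def test_separated_slopes_rejected(self):
        # the 22 vs 15 mV contrast at the printed group sizes (29 vs 16)
        rng = np.random.default_rng(5)
        t_rej = chow_rej = 0
        for _ in range(20):
            Ga, Ia = self._group(rng, 29, 22.0)
            Gb, Ib = self._group(rng, 16, 15.0)
            cmp = compare_slopes(Ga, Ia, Gb, Ib)
            t_rej += cmp.t_pvalue < 0.05
            chow_rej += cmp.chow_pvalue < 0.05
        assert t_rej > 10 and chow_rej > 10

    def test_residual_normality_reported(self):
        rng = np.random.default_rng(2)
        Ga, Ia = self._group(rng, 25, 22.0)
        Gb, Ib = self._group(rng, 25, 22.0)
        cmp = compare_slopes(Ga, Ia, Gb, Ib)
        assert 0.0 < cmp.shapiro_p_a <= 1.0
        assert 0.0 < cmp.shapiro_p_b <= 1.0

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(9)
        n_sim = 1500
        t_rej = chow_rej = 0
        for _ in range(n_sim):
            Ga, Ia = self._group(rng, 20, 20.0)
            Gb, Ib = self._group(rng, 20, 20.0)
            cmp = compare_slopes(Ga, Ia, Gb, Ib)
            t_rej += cmp.t_pvalue < 0.05
            chow_rej += cmp.chow_pvalue < 0.05
        assert 0.03 <= t_rej / n_sim <= 0.07
        assert 0.03 <= chow_rej / n_sim <= 0.07

    def test_insufficient_points_rejected(self):
        with pytest.raises(ValidationError):
            compare_slopes([1, 2], [0.1, 0.2], [1, 2, 3], [0.1, 0.2, 0.3])


def test_tests_invariant_to_reordering():
    rng = np.random.default_rng(4)
    a, b = rng.normal(0, 1, 20), rng.normal(0.3, 1, 15)
    perm = rng.permutation(20)
    assert mann_whitney(a, b) == mann_whitney(a[perm], b)
    assert ks_test(a, b) == ks_test(a[perm], b)
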