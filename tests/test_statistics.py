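import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from hepanorm.cohort import Sex
from hepanorm.stats import (
    TestName as StatTestName,
    TestResult as StatTestResult,
    mann_whitney_gender,
    mann_whitney_u,
    pearson_age,
    simple_linear_regression,
)


def brute_force_u(x, y):
    """Independent oracle: count of (x > y) pairs plus half the ties."""
    u = 0.0
    for xi in x:
        for yi in y:
            if xi > yi:
                u += 1.0
            elif xi == yi:
                u += 0.5
    return u


class TestMannWhitney:
    def test_identical_groups(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        # oracle: 3 wins + 3 half-ties out of 9 pairs
        assert res.statistic == pytest.approx(4.5)
        assert res.p_value == pytest.approx(1.0)

    def test_complete_separation(self):
        res = mann_whitney_u([1, 2, 3], [10, 11, 12])
        assert res.statistic == 0.0
        assert res.p_value < 0.2  # n=3 per group: exact p = 2/20

    def test_complete_separation_exact_p(self):
        # C(6,3) = 20 assignments; only the 2 extreme splits reach |U - 4.5| = 4.5
        res = mann_whitney_u([1, 2, 3], [10, 11, 12])
        assert res.p_value == pytest.approx(2 / 20)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_u([], [1.0])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            mann_whitney_u([np.nan, 1.0], [2.0, 3.0])

    def test_u_matches_brute_force_randomized(self, rng):
        for _ in range(300):
            n1 = int(rng.integers(1, 31))
            n2 = int(rng.integers(1, 31))
            # ties likely: integer-valued draws
            x = rng.integers(0, 10, size=n1).astype(float)
            y = rng.integers(0, 10, size=n2).astype(float)
            res = mann_whitney_u(x, y)
            assert res.statistic == pytest.approx(brute_force_u(x, y))

    def test_p_matches_scipy_asymptotic_no_ties(self, rng):
        for _ in range(50):
            x = rng.normal(size=20)
            y = rng.normal(0.5, size=25)
            res = mann_whitney_u(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_p_matches_subset_enumeration_with_ties(self, rng):
        # independent oracle: enumerate every group-1 index subset directly
        from itertools import combinations

        for _ in range(20):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 7))
            pooled = rng.integers(0, 4, size=n1 + n2).astype(float)
            x, y = pooled[:n1], pooled[n1:]
            res = mann_whitney_u(x, y)
            ranks = sps.rankdata(pooled)
            mid = n1 * n2 / 2.0
            offset = n1 * (n1 + 1) / 2.0
            u_all = [ranks[list(idx)].sum() - offset
                     for idx in combinations(range(n1 + n2), n1)]
            dev = abs(res.statistic - mid)
            expected = np.mean([abs(u - mid) >= dev - 1e-9 for u in u_all])
            assert res.p_value == pytest.approx(expected, rel=1e-12)

    def test_p_matches_scipy_exact_small_no_ties(self, rng):
        for _ in range(25):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            res = mann_whitney_u(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_gender_wrapper_groups_by_sex(self):
        values = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]
        sexes = [Sex.FEMALE] * 3 + [Sex.MALE] * 3
        res = mann_whitney_gender(values, sexes)
        assert res.statistic == 0.0
        assert res.n == (3, 3)

    def test_significant_flag(self):
        res = mann_whitney_u(list(range(10)), list(range(20, 30)))
        assert res.significant == (res.p_value < res.alpha)
        relaxed = mann_whitney_u(list(range(10)), list(range(20, 30)), alpha=1e-9)
        assert not relaxed.significant


class TestPearson:
    def test_perfect_positive_line(self):
        ages = [20.0, 30.0, 40.0, 50.0]
        vals = [1.0, 2.0, 3.0, 4.0]
        res = pearson_age(vals, ages)
        assert res.effect.r == pytest.approx(1.0)
        assert res.effect.r_squared == pytest.approx(1.0)

    def test_symmetric_tent_zero_correlation(self):
        res = pearson_age([0.0, 1.0, 0.0], [0.0, 1.0, 2.0])
        assert res.effect.r == pytest.approx(0.0, abs=1e-12)

    def test_independence_near_zero_r(self, rng):
        ages = rng.uniform(17, 86, size=1000)
        vals = 2.0 + rng.normal(0, 0.3, size=1000)
        res = pearson_age(vals, ages)
        assert abs(res.effect.r) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pearson_age([1.0, 1.0, 1.0], [20.0, 30.0, 40.0])

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 3"):
            pearson_age([1.0, 2.0], [20.0, 30.0])

    def test_matches_t_transform(self, rng):
        ages = rng.uniform(17, 86, size=40)
        vals = 3.0 - 0.01 * ages + rng.normal(0, 0.2, size=40)
        res = pearson_age(vals, ages)
        r, n = res.effect.r, 40
        t = r * np.sqrt((n - 2) / (1 - r * r))
        p = 2 * sps.t.sf(abs(t), n - 2)
        assert res.p_value == pytest.approx(p, rel=1e-9)


class TestLinearRegression:
    def test_exact_line(self):
        res = simple_linear_regression([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])
        assert res.effect.slope == pytest.approx(1.0)
        assert res.effect.intercept == pytest.approx(1.0)

    def test_degenerate_design(self):
        with pytest.raises(ValueError, match="degenerate"):
            simple_linear_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0, max_value=100, allow_nan=False),
                st.floats(min_value=0.1, max_value=10, allow_nan=False),
            ),
            min_size=4,
            max_size=30,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_slope_r_identity(self, pts):
        ages = np.array([p[0] for p in pts])
        vals = np.array([p[1] for p in pts])
        if np.std(ages) < 1e-6 or np.std(vals) < 1e-6:
            return
        res = simple_linear_regression(vals, ages)
        # closed-form identity: slope * sd_age / sd_value == r
        expected_r = res.effect.slope * np.std(ages, ddof=1) / np.std(vals, ddof=1)
        assert res.effect.r == pytest.approx(expected_r, rel=1e-7, abs=1e-9)
        assert res.effect.r_squared == pytest.approx(res.effect.r**2, abs=1e-12)

    def test_slope_sign_matches_pearson(self, rng):
        ages = rng.uniform(17, 86, size=50)
        vals = 2.5 - 0.006 * ages + rng.normal(0, 0.1, size=50)
        reg = simple_linear_regression(vals, ages)
        cor = pearson_age(vals, ages)
        assert np.sign(reg.effect.slope) == np.sign(cor.effect.r)
        assert reg.effect.r_squared == pytest.approx(cor.effect.r_squared, rel=1e-12)


class TestResultContract:
    def test_p_value_bounds_enforced(self):
        with pytest.raises(ValueError):
            StatTestResult(test_name=StatTestName.PEARSON, statistic=0.0, p_value=1.5, n=(3,))
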