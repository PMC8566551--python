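"""Correlation, trend, paired comparison and normality tests, checked
against enumeration oracles and distributional properties."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from amphiphen.stats import (mann_kendall, paired_region_test,
                             pearson_correlation, shapiro_wilk)


def perm_p_pearson(x, y):
    """Exact two-sided permutation p for |r| by full enumeration."""
    r_obs = abs(np.corrcoef(x, y)[0, 1])
    hits = total = 0
    for perm in itertools.permutations(y):
        hits += abs(np.corrcoef(x, perm)[0, 1]) >= r_obs - 1e-12
        total += 1
    return hits / total


class TestPearson:
    def test_perfect_line(self):
        x = np.arange(10.0)
        res = pearson_correlation(x, 2 * x + 1)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value < 1e-10

    def test_perfect_negative(self):
        res = pearson_correlation([1, 2, 3], [3, 2, 1])
        assert res.statistic == pytest.approx(-1.0)

    def test_matches_exact_permutation_p(self):
        """t-transform p vs full 720-permutation enumeration at n = 6."""
        rng = np.random.default_rng(12345)
        diffs = []
        for _ in range(8):
            x, y = rng.normal(size=6), rng.normal(size=6)
            res = pearson_correlation(x, y)
            diffs.append(abs(res.p_value - perm_p_pearson(x, y)))
        # the first-drawn pair, and the typical (mean) agreement
        assert diffs[0] < 0.02
        assert np.mean(diffs) < 0.02

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=12), rng.normal(size=12)
        r_xy = pearson_correlation(x, y)
        r_yx = pearson_correlation(y, x)
        assert r_xy.statistic == pytest.approx(r_yx.statistic)
        scaled = pearson_correlation(3 * x + 7, -2 * y + 1)
        assert scaled.statistic == pytest.approx(-r_xy.statistic)
        assert scaled.p_value == pytest.approx(r_xy.p_value)


class TestMannKendall:
    def test_strictly_increasing(self):
        res = mann_kendall([(2000 + i, 50 + i) for i in range(6)], method="normal")
        assert res.extras["tau"] == pytest.approx(1.0)
        assert res.extras["S"] == 15  # n(n-1)/2

    def test_all_tied_degenerate(self):
        res = mann_kendall([(2000 + i, 70) for i in range(6)], method="normal")
        assert res.extras["S"] == 0
        assert res.p_value == 1.0

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="n >= 4"):
            mann_kendall([(2000, 1), (2001, 2), (2002, 3)])

    def test_normal_approx_close_to_exact_enumeration(self):
        """Continuity-corrected normal p vs the full 7! permutation
        distribution of S, for random length-7 series."""
        rng = np.random.default_rng(12345)
        for _ in range(5):
            series = [(2000 + i, v) for i, v in enumerate(rng.normal(size=7))]
            res = mann_kendall(series, method="exact")
            assert abs(res.extras["p_normal"] - res.extras["p_exact"]) < 0.02

    def test_tau_matches_scipy_kendalltau(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=15)
        res = mann_kendall([(2000 + i, x) for i, x in enumerate(v)], method="normal")
        tau_b, _ = sps.kendalltau(np.arange(15), v)
        assert res.extras["tau"] == pytest.approx(tau_b, abs=1e-12)  # no ties here

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        v = rng.uniform(1, 10, size=9)
        a = mann_kendall([(2000 + i, x) for i, x in enumerate(v)])
        b = mann_kendall([(2000 + i, np.exp(x)) for i, x in enumerate(v)])
        assert a.p_value == pytest.approx(b.p_value)
        assert a.extras["S"] == b.extras["S"]

    def test_year_order_not_input_order(self):
        shuffled = [(2003, 4), (2000, 1), (2002, 3), (2001, 2), (2004, 5)]
        res = mann_kendall(shuffled, method="normal")
        assert res.extras["tau"] == pytest.approx(1.0)


class TestPairedRegions:
    def _series(self, values, years=None):
        years = years or range(2000, 2000 + len(values))
        return pd.DataFrame({"year": list(years), "onset_doy": values})

    def test_constant_shift_flagged_exact(self):
        a = self._series([70, 75, 80])
        b = self._series([75, 80, 85])
        res = paired_region_test(a, b)
        assert res.extras["mean_difference"] == pytest.approx(-5.0)
        assert res.extras["exact_difference"] is True
        assert res.p_value == 0.0

    def test_identical_series(self):
        a = self._series([70, 75, 80])
        res = paired_region_test(a, a)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_scipy_on_noisy_data(self):
        rng = np.random.default_rng(4)
        a = self._series(rng.normal(80, 3, 10))
        b = self._series(rng.normal(76, 3, 10))
        res = paired_region_test(a, b)
        t, p = sps.ttest_rel(a["onset_doy"], b["onset_doy"])
        assert res.statistic == pytest.approx(t) and res.p_value == pytest.approx(p)

    def test_power_for_nine_day_regional_shift(self):
        """A 9-day cool-vs-moderate shift with sd 3 at n = 15 years is
        detected at alpha = 0.05 in >= 95% of simulations."""
        rng = np.random.default_rng(2718)
        hits = 0
        for _ in range(200):
            base = rng.normal(80, 4, 15)
            a = self._series(base + 9 + rng.normal(0, 3, 15))
            b = self._series(base + rng.normal(0, 3, 15))
            hits += paired_region_test(a, b).p_value < 0.05
        assert hits >= 0.95 * 200


class TestShapiroWilk:
    def test_p_uniform_under_normality(self):
        """KS check: Shapiro p over 200 normal samples is ~ Uniform(0,1)."""
        rng = np.random.default_rng(5)
        ps = [shapiro_wilk(rng.normal(size=50)).p_value for _ in range(200)]
        ks = sps.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_detects_heavy_skew(self):
        rng = np.random.default_rng(6)
        rejections = sum(shapiro_wilk(rng.exponential(size=50)).p_value < 0.05
                         for _ in range(100))
        assert rejections >= 95

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="variance"):
            shapiro_wilk([3.0] * 10)
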