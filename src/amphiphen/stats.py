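"""Descriptive and inferential tests on onset series.

Normality (Shapiro-Wilk), paired regional comparison (paired t), monotone
trend over years (Mann-Kendall with tie-corrected variance and continuity
correction, exact permutation p for short series), and plant-amphibian
association (two-tailed Pearson product-moment correlation).  All pipeline
reports evaluate at alpha = 0.05; no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n: int
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def pearson_correlation(x, y) -> TestResult:
    """Two-tailed Pearson product-moment correlation (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return TestResult(statistic=float(r), p_value=float(p), n=len(x))


def _mk_s_tau(values: np.ndarray):
    diff = np.sign(values[None, :] - values[:, None])
    s = int(np.triu(diff, 1).sum())
    n = len(values)
    tau = s / (n * (n - 1) / 2)
    return s, tau


def mann_kendall(series, method: str = "auto") -> TestResult:
    """Mann-Kendall trend test on a (year, onset_doy) series.

    S = sum_{i<j} sign(x_j - x_i) over the year-ordered values; var(S) uses
    the standard tie-group correction; z is continuity-corrected; tau is
    S / (n(n-1)/2).  ``method``: "normal", "exact" (full permutation
    distribution of S, n <= 10), or "auto" (exact when n <= 10).  The exact
    p is also reported in ``extras['p_exact']`` whenever computed.
    """
    if isinstance(series, pd.DataFrame):
        df = series.sort_values("year")
        values = df["onset_doy"].to_numpy(dtype=float)
    else:
        arr = sorted((int(yr), float(v)) for yr, v in series)
        values = np.array([v for _, v in arr])
    n = len(values)
    if n < 4:
        raise ValueError("Mann-Kendall needs n >= 4")
    s, tau = _mk_s_tau(values)
    _, counts = np.unique(values, return_counts=True)
    ties = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var_s <= 0:  # all values tied
        z, p_normal = 0.0, 1.0
    else:
        z = (s - np.sign(s)) / np.sqrt(var_s)
        p_normal = 2 * sps.norm.sf(abs(z))
    extras = {"S": float(s), "var_S": float(var_s), "z": float(z), "tau": float(tau)}
    p = p_normal
    if method == "exact" or (method == "auto" and n <= 10):
        p_exact = _mk_exact_p(values, s)
        extras["p_exact"] = p_exact
        p = p_exact
    extras["p_normal"] = float(p_normal)
    return TestResult(statistic=float(z), p_value=float(p), n=n, extras=extras)


def _mk_exact_p(values: np.ndarray, s_obs: int) -> float:
    """Exact two-sided p: share of orderings with |S| >= |S observed|."""
    n = len(values)
    if n > 10:
        raise ValueError("exact Mann-Kendall limited to n <= 10")
    hits = 0
    total = 0
    for perm in permutations(values):
        s, _ = _mk_s_tau(np.asarray(perm))
        hits += abs(s) >= abs(s_obs)
        total += 1
    return hits / total


def paired_region_test(series_a: pd.DataFrame, series_b: pd.DataFrame) -> TestResult:
    """Paired t-test on within-year onset differences between two regions.

    Inputs carry columns (year, onset_doy) for the same taxon; rows are
    matched by year.  With zero variance in the differences the t statistic
    is undefined: the result carries ``extras['exact_difference']=True`` and
    p is 1 when the constant difference is zero, else 0 (the shift is
    reproduced in every matched year).
    """
    m = series_a.merge(series_b, on="year", suffixes=("_a", "_b"))
    if len(m) < 2:
        raise ValueError("paired test needs at least 2 matched years")
    d = (m["onset_doy_a"] - m["onset_doy_b"]).to_numpy(dtype=float)
    extras = {"mean_difference": float(d.mean())}
    if np.ptp(d) == 0:
        extras["exact_difference"] = True
        p = 1.0 if d.mean() == 0 else 0.0
        return TestResult(statistic=0.0 if d.mean() == 0 else np.inf * np.sign(d.mean()),
                          p_value=p, n=len(d), extras=extras)
    t, p = sps.ttest_rel(m["onset_doy_a"], m["onset_doy_b"])
    return TestResult(statistic=float(t), p_value=float(p), n=len(d), extras=extras)


def shapiro_wilk(values) -> TestResult:
    """Shapiro-Wilk normality diagnostic (never used as a gate)."""
    x = np.asarray(values, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("zero variance: Shapiro-Wilk undefined")
    w, p = sps.shapiro(x)
    return TestResult(statistic=float(w), p_value=float(p), n=len(x))


def trend_report(start_dates: pd.DataFrame) -> pd.DataFrame:
    """Mann-Kendall per taxon (regions pooled by earliest onset per year)."""
    rows = []
    for taxon, sub in start_dates.groupby("taxon"):
        series = sub.groupby("year")["onset_doy"].min().reset_index()
        if len(series) < 4:
            continue
        res = mann_kendall(series, method="auto")
        rows.append({"taxon": taxon, "n": res.n, "S": res.extras["S"],
                     "tau": res.extras["tau"], "z": res.statistic,
                     "p_value": res.p_value,
                     "significant_at_0.05": res.p_value < ALPHA})
    return pd.DataFrame(rows)


def correlation_report(paired_tables: dict) -> pd.DataFrame:
    """Pearson r per (amphibian, plant) pair from pooled paired tables."""
    rows = []
    for (amph, plant), table in paired_tables.items():
        if len(table) < 3:
            continue
        res = pearson_correlation(table["plant_doy"], table["amphibian_doy"])
        rows.append({"amphibian": amph, "plant": plant, "n": res.n,
                     "r": res.statistic, "p_value": res.p_value,
                     "significant_at_0.05": res.p_value < ALPHA})
    return pd.DataFrame(rows)
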