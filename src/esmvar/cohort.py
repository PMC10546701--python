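"""Baseline cohort statistics for group comparisons.

Desk-scale frequentist statistics used to characterise the diagnostic
groups before the dynamic modelling: 2x2 chi-square with Yates continuity
correction, Wald odds-ratio intervals, exact Fisher tests for r x c count
tables (full enumeration with two-sided probability ordering), one-way
ANOVA with the omega-squared effect size and its noncentral-F confidence
interval, and Tukey HSD pairwise contrasts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq


def _as_2x2(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    return t


def chisq_2x2(table, corrected: bool = True) -> tuple[float, int, float]:
    """Pearson chi-square for a 2x2 table, Yates-corrected by default.

    With the continuity correction, |ad - bc| is reduced by N/2 (floored at
    zero) before squaring.  A zero row or column margin leaves the statistic
    undefined (NaN, with a warning).
    """
    t = _as_2x2(table)
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    if n <= 0:
        raise ValueError("empty table")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        warnings.warn("zero margin: chi-square undefined", RuntimeWarning, stacklevel=2)
        return math.nan, 1, math.nan
    diff = abs(a * d - b * c)
    if corrected:
        diff = max(diff - n / 2.0, 0.0)
    stat = n * diff * diff / (r1 * r2 * c1 * c2)
    return float(stat), 1, float(stats.chi2.sf(stat, 1))


def odds_ratio_wald(table, level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Odds ratio (a*d)/(b*c) with a Wald log-scale confidence interval.

    Zero cells trigger the Haldane-Anscombe +0.5 correction (warned).  The
    orientation follows the caller's table: row 1 odds over row 2 odds.
    """
    t = _as_2x2(table)
    if np.any(t == 0):
        warnings.warn(
            "zero cell: applying Haldane-Anscombe +0.5 correction",
            RuntimeWarning,
            stacklevel=2,
        )
        t = t + 0.5
    a, b = t[0]
    c, d = t[1]
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo, hi = math.exp(math.log(or_) - z * se), math.exp(math.log(or_) + z * se)
    return float(or_), (float(lo), float(hi))


def _log_table_prob(counts: np.ndarray, row_sums, col_sums, n) -> float:
    s = sum(math.lgamma(m + 1) for m in row_sums)
    s += sum(math.lgamma(m + 1) for m in col_sums)
    s -= math.lgamma(n + 1)
    s -= sum(math.lgamma(x + 1) for x in counts)
    return s


def fisher_exact(table, max_tables: int = 2_000_000) -> float:
    """Exact two-sided Fisher test for an r x c count table.

    Enumerates every table with the observed margins and sums the
    probabilities of tables no more probable than the observed one
    (probability-ordering two-sided rule, as in R's ``fisher.test``).
    Raises if the enumeration would exceed ``max_tables`` candidate tables.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or np.any(t < 0):
        raise ValueError("expected a nonnegative integer r x c table")
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    n = int(t.sum())
    if n == 0:
        raise ValueError("empty table")
    # rough enumeration bound: product over free cells of (margin + 1)
    bound = 1
    for r in row_sums[:-1]:
        for c in col_sums[:-1]:
            bound *= min(r, c) + 1
            if bound > max_tables:
                raise ValueError("table too large for exact enumeration")
    lp_obs = _log_table_prob(t.ravel(), row_sums, col_sums, n)
    r_, c_ = t.shape
    p_total = 0.0
    p_tail = 0.0

    cells = np.zeros((r_, c_), dtype=int)

    def rec(i: int, j: int, row_left, col_left):
        nonlocal p_total, p_tail
        if i == r_ - 1:
            # last row forced by column margins
            last = col_left.copy()
            if np.any(last < 0):
                return
            cells[r_ - 1] = last
            lp = _log_table_prob(cells.ravel(), row_sums, col_sums, n)
            pr = math.exp(lp)
            p_total += pr
            if lp <= lp_obs + 1e-7:
                p_tail += pr
            return
        if j == c_ - 1:
            v = row_left[i]
            if v < 0 or v > col_left[j]:
                return
            cells[i, j] = v
            col_left2 = col_left.copy()
            col_left2[j] -= v
            row_left2 = row_left.copy()
            row_left2[i] = 0
            rec(i + 1, 0, row_left2, col_left2)
            return
        for v in range(min(row_left[i], col_left[j]) + 1):
            cells[i, j] = v
            col_left2 = col_left.copy()
            col_left2[j] -= v
            row_left2 = row_left.copy()
            row_left2[i] -= v
            rec(i, j + 1, row_left2, col_left2)

    rec(0, 0, row_sums.copy(), col_sums.copy())
    # p_total ~ 1 up to float error; normalise defensively
    return float(min(p_tail / p_total, 1.0))


@dataclass
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    omega_sq: float
    omega_sq_ci: tuple[float, float]


def oneway_anova_omega(samples: list[np.ndarray], level: float = 0.95) -> AnovaResult:
    """One-way ANOVA with omega-squared and its noncentral-F interval.

    omega^2 = (SSB - dfB * MSW) / (SST + MSW), clipped at zero.  The CI
    inverts the noncentral-F distribution for the noncentrality lambda and
    maps it through omega^2 = lambda / (lambda + N).
    """
    groups = [np.asarray(g, dtype=float) for g in samples]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    n_tot = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = n_tot - len(groups)
    if df_w <= 0 or ssw == 0:
        raise ValueError("within-group variance undefined")
    msw = ssw / df_w
    f = (ssb / df_b) / msw
    p = float(stats.f.sf(f, df_b, df_w))
    omega_sq = max((ssb - df_b * msw) / (ssb + ssw + msw), 0.0)
    alpha = 1.0 - level

    def lam_bound(prob: float) -> float:
        # largest lambda with P(F >= f | lambda) <= prob  (via cdf inversion)
        def g(lam):
            return stats.ncf.cdf(f, df_b, df_w, lam) - prob
        if g(0.0) <= 0:
            return 0.0
        hi = 4.0
        while g(hi) > 0 and hi < 1e6:
            hi *= 2.0
        return brentq(g, 0.0, hi)

    lam_lo = lam_bound(1.0 - alpha / 2.0)
    lam_hi = lam_bound(alpha / 2.0)
    ci = (lam_lo / (lam_lo + n_tot), lam_hi / (lam_hi + n_tot))
    return AnovaResult(float(f), df_b, df_w, p, float(omega_sq), (float(ci[0]), float(ci[1])))


def tukey_hsd(samples: list[np.ndarray], level: float = 0.95) -> pd.DataFrame:
    """Tukey HSD pairwise mean contrasts (studentized-range based).

    Returns one row per group pair with the mean difference, simultaneous
    confidence bounds at ``level``, and the adjusted p-value.
    """
    groups = [np.asarray(g, dtype=float) for g in samples]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    res = stats.tukey_hsd(*groups)
    ci = res.confidence_interval(confidence_level=level)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append(
                {
                    "group_i": i,
                    "group_j": j,
                    "difference": float(groups[i].mean() - groups[j].mean()),
                    "ci_low": float(ci.low[i, j]),
                    "ci_high": float(ci.high[i, j]),
                    "p": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)
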