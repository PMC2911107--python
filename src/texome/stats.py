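"""The statistical procedures used throughout the analyses.

Pearson contingency-table and goodness-of-fit chi-square statistics are
computed from their closed forms without continuity correction (the
comparisons here are large-count; the Yates correction is deliberately
not applied anywhere).  The 2x2 Fisher exact test sums hypergeometric
probabilities with exact integer arithmetic, so ties are handled without
floating-point ambiguity.  Kolmogorov-Smirnov (normality screen) and the
two-sample t-test (Welch by default) delegate to scipy.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .core import StatResult, UndefinedStatisticError


def chi2_contingency(table) -> StatResult:
    """Pearson chi-square for an r x c count table (no Yates correction).

    Expected counts come from the margins; dof = (r-1)(c-1); the p-value
    is the upper chi-square tail.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.min() < 0:
        raise UndefinedStatisticError("table must be 2-D with non-negative counts")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    n = obs.sum()
    if (rows == 0).any() or (cols == 0).any() or n == 0:
        raise UndefinedStatisticError("degenerate table: zero row or column sum")
    expected = np.outer(rows, cols) / n
    stat = float(((obs - expected) ** 2 / expected).sum())
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, dof)) if dof > 0 else 1.0
    return StatResult(stat, min(p, 1.0), "chi2_contingency", dof)


def fisher_exact_2x2(table) -> StatResult:
    """Two-sided Fisher exact test for a 2x2 table.

    The p-value sums, over the hypergeometric support with the observed
    margins, the probabilities of all tables no more probable than the
    observed one; probabilities are compared as exact integers.  The
    statistic is the sample odds ratio (NaN when undefined).
    """
    (a, b), (c, d) = ((int(x) for x in row) for row in table)
    if min(a, b, c, d) < 0:
        raise UndefinedStatisticError("counts must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    odds = (a * d) / (b * c) if b * c != 0 else float("nan")
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return StatResult(odds, 1.0, "fisher_exact")
    lo, hi = max(0, c1 - r2), min(c1, r1)
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    obs_w = weights[a - lo]
    num = sum(w for w in weights if w <= obs_w)
    p = float(Fraction(num, math.comb(n, c1)))
    return StatResult(odds, min(p, 1.0), "fisher_exact")


def chi2_goodness_of_fit(observed, expected_probs) -> StatResult:
    """Chi-square goodness of fit of counts against expected proportions."""
    obs = np.asarray(observed, dtype=float)
    probs = np.asarray(expected_probs, dtype=float)
    if obs.shape != probs.shape or obs.ndim != 1:
        raise UndefinedStatisticError("observed and expected_probs must match in shape")
    if obs.min() < 0 or probs.min() <= 0:
        raise UndefinedStatisticError("counts must be >= 0 and probabilities > 0")
    probs = probs / probs.sum()
    n = obs.sum()
    if n == 0:
        raise UndefinedStatisticError("no observations")
    expected = n * probs
    stat = float(((obs - expected) ** 2 / expected).sum())
    dof = len(obs) - 1
    p = float(sps.chi2.sf(stat, dof)) if dof > 0 else 1.0
    return StatResult(stat, min(p, 1.0), "chi2_goodness_of_fit", dof)


def ks_normality(sample: Sequence[float]) -> StatResult:
    """Kolmogorov-Smirnov screen against a normal distribution.

    The sample is standardised by its own mean and standard deviation
    first (with estimated parameters the test is conservative; it is
    used here only as a distribution screen before the t-test).
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 3 or x.std(ddof=1) == 0:
        raise UndefinedStatisticError("need >= 3 values with nonzero spread")
    z = (x - x.mean()) / x.std(ddof=1)
    res = sps.kstest(z, "norm")
    return StatResult(float(res.statistic), float(res.pvalue), "ks_normality")


def t_test_two_sample(a, b, equal_var: bool = False) -> StatResult:
    """Two-sample t-test (Welch by default)."""
    res = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=equal_var)
    return StatResult(float(res.statistic), float(res.pvalue), "t_test")
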