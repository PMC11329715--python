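"""Population-level statistics: OLS fits, Wilcoxon rank-sum, pairwise contrasts.

These mirror the comparative analyses of the study: linear models of
preferred temperature on size and latitude, rank-sum tests for sex, gravidity
and scenario contrasts, and multiplicity-adjusted pairwise population
comparisons from a one-factor linear model.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, InsufficientDataError

__all__ = [
    "FitResult",
    "ols_fit",
    "wilcoxon_ranksum",
    "pairwise_population_comparison",
]

#: largest m*n for which the tie-free rank-sum test is enumerated exactly
EXACT_WILCOXON_LIMIT = 400


@dataclass(frozen=True)
class FitResult:
    slope: float
    intercept: float
    slope_se: float
    t_stat: float
    p_value: float
    n: int


def ols_fit(x, y) -> FitResult:
    """Simple least-squares regression of y on x with a two-sided slope test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("need n >= 3")
    if np.ptp(x) == 0:
        raise DegenerateInputError("x is constant: slope undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return FitResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_se=float(model.bse[1]),
        t_stat=float(model.tvalues[1]),
        p_value=float(model.pvalues[1]),
        n=int(x.size),
    )


def wilcoxon_ranksum(a, b):
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    W is the count-of-wins statistic for the first sample (number of pairs
    where a > b, ties counting one half).  Small tie-free samples
    (m*n <= 400) are enumerated exactly; otherwise the normal approximation
    with continuity and tie correction is used.  Returns (W, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (a.size * b.size <= EXACT_WILCOXON_LIMIT) and not has_ties
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(res.statistic), float(res.pvalue)


def pairwise_population_comparison(
    values_by_group: dict, adjustment: str = "holm"
) -> pd.DataFrame:
    """All pairwise group contrasts from a one-factor linear model.

    Pooled-variance t statistics on the group-mean differences with
    ``holm`` (default) or ``bonferroni`` adjustment (the Bonferroni option is
    the dependency-free stand-in for a single-step multivariate-normal bound).
    Returns a table with columns group_a, group_b, estimate, t_stat, p_raw,
    p_adj, method.
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise InsufficientDataError("need at least 2 groups")
    arrs = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    n_total = sum(a.size for a in arrs.values())
    k = len(groups)
    df = n_total - k
    if df < 1:
        raise InsufficientDataError("no residual degrees of freedom")
    sse = sum(((a - a.mean()) ** 2).sum() for a in arrs.values())
    s2 = sse / df  # pooled residual variance
    if adjustment not in {"holm", "bonferroni"}:
        raise ValueError(f"unknown adjustment {adjustment!r}")

    rows = []
    for ga, gb in combinations(groups, 2):
        xa, xb = arrs[ga], arrs[gb]
        est = xa.mean() - xb.mean()
        se = np.sqrt(s2 * (1 / xa.size + 1 / xb.size))
        if se == 0:
            t = 0.0 if est == 0 else np.inf * np.sign(est)
        else:
            t = est / se
        p = 2 * stats.t.sf(abs(t), df) if np.isfinite(t) else 0.0
        rows.append({"group_a": ga, "group_b": gb, "estimate": float(est),
                     "t_stat": float(t), "p_raw": float(p)})
    tab = pd.DataFrame(rows)
    tab["p_adj"] = multipletests(tab["p_raw"], method=adjustment)[1]
    tab["method"] = adjustment
    return tab
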