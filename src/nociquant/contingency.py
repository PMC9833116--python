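"""Exact contingency inference, multiplicity adjustment and reporting.

Responder counts from calcium-imaging cohorts arrive as r x 2 tables
(responders / non-responders across stimulus groups).  The 2 x 2 case uses
the two-sided Fisher exact test in the point-probability convention (sum
the hypergeometric probabilities of all tables, with the observed margins,
that are no more probable than the observed one); the r x 2 case uses the
Freeman-Halton extension, enumerated exactly when the total count permits
and otherwise approximated by Monte-Carlo sampling of tables with the
observed margins.  Holm step-down and Benjamini-Yekutieli adjustments and
a one-way ANOVA with Bonferroni-adjusted pairwise Welch comparisons cover
the remaining small-sample comparisons, and a report generator turns
responder counts into the rounded percentages quoted in results text.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "fisher_exact_2x2",
    "fisher_exact_rx2",
    "holm_adjust",
    "bh_yekutieli_adjust",
    "anova_oneway_bonferroni",
    "percent",
    "responder_report",
]

#: relative slack when comparing floating-point table probabilities
_TIE_SLACK = 1e-7


@dataclass(frozen=True)
class TestResult:
    statistic: float | None
    p: float
    method: str
    df: float | None = None
    q: float | None = None
    mc_standard_error: float | None = None
    extra: tuple = ()


def _check_2x2(table) -> np.ndarray:
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.floor(t)):
            raise ValueError("counts must be non-negative integers")
    t = t.astype(np.int64)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin: test undefined")
    return t


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 count table.

    Point-probability convention: p sums the probabilities of all tables
    with the observed margins whose probability does not exceed the
    observed one (to within a small float-tie slack); this matches the
    convention of mainstream statistical environments.
    """
    t = _check_2x2(table)
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return TestResult(statistic=float(odds), p=float(p), method="fisher_exact_2x2")


def _log_table_prob(col1: np.ndarray, rows: np.ndarray, c1: int, c2: int, n: int) -> float:
    """Log multivariate hypergeometric probability of an r x 2 table.

    ``col1`` holds the first-column entries; row margins ``rows`` and
    column margins (c1, c2) are fixed.
    """
    lp = lgamma(c1 + 1) + lgamma(c2 + 1) - lgamma(n + 1)
    for ri, a in zip(rows, col1):
        lp += lgamma(ri + 1) - lgamma(a + 1) - lgamma(ri - a + 1)
    return lp


def fisher_exact_rx2(table, max_exact_total: int = 3000, n_mc: int = 200_000,
                     seed: int = 0) -> TestResult:
    """Freeman-Halton exact test for an r x 2 table (r <= 4).

    Enumerates every table with the observed margins and sums the
    probabilities of those no more probable than the observed table.  When
    the grand total exceeds ``max_exact_total`` the p-value is instead
    estimated by Monte-Carlo sampling of margin-preserving tables, with the
    standard error reported.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[1] != 2:
        raise ValueError("need an r x 2 table")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    r = t.shape[0]
    if r > 4:
        raise ValueError("r <= 4 supported")
    rows = t.sum(axis=1)
    c1, c2 = t.sum(axis=0)
    n = int(t.sum())
    if np.any(rows == 0) or c1 == 0 or c2 == 0:
        raise ValueError("zero margin: test undefined")
    if r == 2:
        return fisher_exact_2x2(t)

    lp_obs = _log_table_prob(t[:, 0], rows, c1, c2, n)
    cut = lp_obs + np.log1p(_TIE_SLACK)

    if n <= max_exact_total:
        total = 0.0
        if r == 3:
            a0_lo = max(0, c1 - rows[1] - rows[2])
            for a0 in range(a0_lo, min(rows[0], c1) + 1):
                rem = c1 - a0
                a1_lo = max(0, rem - rows[2])
                for a1 in range(a1_lo, min(rows[1], rem) + 1):
                    col1 = np.array([a0, a1, rem - a1])
                    lp = _log_table_prob(col1, rows, c1, c2, n)
                    if lp <= cut:
                        total += np.exp(lp)
        else:  # r == 4
            for a0 in range(0, min(rows[0], c1) + 1):
                for a1 in range(0, min(rows[1], c1 - a0) + 1):
                    rem = c1 - a0 - a1
                    a2_lo = max(0, rem - rows[3])
                    for a2 in range(a2_lo, min(rows[2], rem) + 1):
                        col1 = np.array([a0, a1, a2, rem - a2])
                        lp = _log_table_prob(col1, rows, c1, c2, n)
                        if lp <= cut:
                            total += np.exp(lp)
        return TestResult(statistic=None, p=float(min(total, 1.0)),
                          method="freeman_halton_exact")

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(rows, c1, size=n_mc)
    lps = np.array([_log_table_prob(d, rows, c1, c2, n) for d in draws])
    hits = lps <= cut
    p = float(hits.mean())
    se = float(np.sqrt(p * (1 - p) / n_mc))
    return TestResult(statistic=None, p=p, method="freeman_halton_mc",
                      mc_standard_error=se)


def holm_adjust(p) -> np.ndarray:
    """Holm step-down familywise-error adjustment."""
    p = _check_p(p)
    return multipletests(p, method="holm")[1]


def bh_yekutieli_adjust(p) -> np.ndarray:
    """Benjamini-Yekutieli dependency-robust FDR adjustment."""
    p = _check_p(p)
    return multipletests(p, method="fdr_by")[1]


def _check_p(p) -> np.ndarray:
    p = np.asarray(list(p), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def anova_oneway_bonferroni(groups: list) -> tuple[TestResult, list[dict]]:
    """One-way ANOVA plus Bonferroni-adjusted pairwise Welch comparisons.

    Returns the omnibus F result and a list of pairwise records
    (i, j, t, p_raw, p_bonferroni).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with n >= 2 each")
    f, p = stats.f_oneway(*groups)
    if np.isnan(f):  # all values identical across groups
        f, p = 0.0, 1.0
    k = len(groups)
    df1 = k - 1
    df2 = sum(len(g) for g in groups) - k
    m = k * (k - 1) // 2
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            res = stats.ttest_ind(groups[i], groups[j], equal_var=False)
            praw = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
            pairs.append(
                dict(i=i, j=j, t=float(np.nan_to_num(res.statistic)),
                     p_raw=praw, p_bonferroni=min(1.0, praw * m))
            )
    return (
        TestResult(statistic=float(f), p=float(p), method="anova_oneway",
                   df=float(df1), extra=(float(df2),)),
        pairs,
    )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def percent(k: int, n: int, decimals: int = 2) -> float:
    """Responder percentage rounded to ``decimals`` with round-half-even."""
    if n <= 0:
        raise ValueError("total must be positive")
    return float(np.round(100.0 * k / n, decimals))


def responder_report(counts: dict, decimals: int = 2) -> str:
    """Markdown report of responder proportions.

    ``counts`` maps a condition label to a (responders, total) pair;
    percentages are computed by pure arithmetic from the counts.
    """
    lines = ["| condition | responders | total | percent |",
             "|---|---|---|---|"]
    for label, (k, n) in counts.items():
        lines.append(f"| {label} | {k} | {n} | {percent(k, n, decimals):.{decimals}f}% |")
    return "\n".join(lines)
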