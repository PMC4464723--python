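"""Nonparametric statistics for cohort comparisons.

Mann-Whitney U for two-group comparisons, Spearman rank correlation for
association, median/IQR group summaries, and integer percentage reporting
(round half away from zero), matching how BAT cohort results are reported.

Exact vs approximate p-values: the Mann-Whitney test enumerates the full
permutation distribution when the pooled sample is small (default
``n_x + n_y <= 12``) and otherwise uses the normal approximation with tie and
continuity corrections.  Spearman's test enumerates all pairings for
``n <= 8`` and uses the t approximation above that.  Both switch points are
package constants, configurable per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "GroupSummary",
    "mann_whitney",
    "spearman",
    "summarize",
    "percent_rounded",
]

MANN_WHITNEY_EXACT_MAX = 12  # pooled-sample size up to which U is enumerated
SPEARMAN_EXACT_MAX = 8  # sample size up to which pairings are enumerated


@dataclass
class TestResult:
    """A test statistic with its two-sided p-value."""

    name: str
    statistic: float
    pvalue: float
    n1: int
    n2: int
    note: str = ""


@dataclass
class GroupSummary:
    """Median / IQR summary of one variable in one group."""

    group: str
    variable: str
    n: int
    median: float
    iqr: float
    q1: float
    q3: float


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{(i, j): x_i > y_j} + 0.5 * #{ties}."""
    ranks = sps.rankdata(np.concatenate([x, y]))
    rx = ranks[: x.size].sum()
    return float(rx - x.size * (x.size + 1) / 2.0)


def mann_whitney(
    x, y, exact_max: int = MANN_WHITNEY_EXACT_MAX
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    U counts pairs with ``x > y`` plus half-credit for ties.  For pooled
    samples up to ``exact_max`` the p-value is exact: every assignment of the
    pooled values to the two groups is enumerated and the two-sided p is the
    permutation probability of a U at least as far from ``n_x * n_y / 2`` as
    observed.  Larger samples use the normal approximation with tie
    correction and a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires non-empty samples")
    n1, n2 = x.size, y.size
    u = _u_statistic(x, y)
    mean = n1 * n2 / 2.0

    if n1 + n2 <= exact_max:
        # U for a labeling depends only on which pooled mid-ranks go to x
        ranks = sps.rankdata(np.concatenate([x, y]))
        offset = n1 * (n1 + 1) / 2.0
        combos = np.fromiter(
            (r for comb in combinations(ranks, n1) for r in comb),
            dtype=float,
        ).reshape(-1, n1)
        u_perm = combos.sum(axis=1) - offset
        dev = abs(u - mean)
        p = float(np.mean(np.abs(u_perm - mean) >= dev - 1e-12))
        return TestResult("mann_whitney_u", u, p, n1, n2, note="exact")

    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return TestResult(
            "mann_whitney_u", u, 1.0, n1, n2, note="degenerate (all values tied)"
        )
    z = (abs(u - mean) - 0.5) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
    return TestResult(
        "mann_whitney_u", u, p, n1, n2,
        note="normal approximation, tie and continuity corrected",
    )


def spearman(x, y, exact_max: int = SPEARMAN_EXACT_MAX) -> TestResult:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of mid-ranks.  Constant input leaves rho
    undefined (NaN, flagged in the note).  Small samples (``n <= exact_max``)
    get an exact permutation p over all pairings; larger samples use the
    t approximation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("spearman requires paired samples of equal length")
    n = x.size
    if n < 3:
        raise ValueError("spearman requires n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult(
            "spearman_rho", float("nan"), float("nan"), n, n,
            note="undefined: constant input",
        )
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n <= exact_max:
        perms = np.fromiter(
            (v for perm in permutations(ry) for v in perm), dtype=float
        ).reshape(-1, n)
        rxc = (rx - rx.mean()) / rx.std()
        pc = perms - perms.mean(axis=1, keepdims=True)
        r_perm = (pc @ rxc) / (n * pc.std(axis=1))
        p = float(np.mean(np.abs(r_perm) >= abs(rho) - 1e-12))
        return TestResult("spearman_rho", rho, p, n, n, note="exact")

    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return TestResult("spearman_rho", rho, p, n, n, note="t approximation")


def summarize(values, group: str = "", variable: str = "") -> GroupSummary:
    """Median and IQR with linear interpolation between order statistics."""
    v = np.asarray(values, dtype=float).ravel()
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("summarize requires at least one non-missing value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return GroupSummary(
        group=group, variable=variable, n=int(v.size),
        median=float(med), iqr=float(q3 - q1), q1=float(q1), q3=float(q3),
    )


def percent_rounded(numerator: int, denominator: int) -> int:
    """Integer percent, rounded half away from zero (as in cohort tables)."""
    if denominator <= 0:
        raise ValueError(f"denominator must be > 0, got {denominator}")
    if not 0 <= numerator <= denominator:
        raise ValueError(
            f"numerator must be in [0, {denominator}], got {numerator}"
        )
    return int(math.floor(100.0 * numerator / denominator + 0.5))
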