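"""Exact and approximate statistical primitives shared across the pipeline.

Four operations: upper-tail binomial test, one-sided Fisher's exact test,
Mann-Whitney U (exact by enumeration for small samples, tie-corrected
normal approximation otherwise), and Benjamini-Hochberg FDR adjustment.
Each is verified against enumeration oracles in the test suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

Alternative = Literal["two-sided", "greater", "less"]

# Exact-vs-approximate crossover for the Mann-Whitney test: C(16, 8) = 12870
# arrangements is cheap to enumerate; beyond that the normal approximation
# with tie and continuity corrections is accurate to a few percent.
EXACT_MWU_MAX_TOTAL = 16


@dataclass(frozen=True)
class BinomialInput:
    """n Bernoulli trials, k successes, success probability p."""

    n: int
    k: int
    p: float

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n:
            raise ValueError(f"require 0 <= k <= n, got k={self.k}, n={self.n}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"require 0 <= p <= 1, got p={self.p}")


@dataclass(frozen=True)
class FisherInput:
    """2x2 table margins: N sequences total, C with the motif, R in the
    target group, x target sequences with the motif."""

    N: int
    C: int
    R: int
    x: int

    def __post_init__(self) -> None:
        if not (0 <= self.C <= self.N and 0 <= self.R <= self.N):
            raise ValueError(f"margins out of range: N={self.N}, C={self.C}, R={self.R}")
        lo, hi = max(0, self.C + self.R - self.N), min(self.C, self.R)
        if not lo <= self.x <= hi:
            raise ValueError(f"x={self.x} outside feasible range [{lo}, {hi}]")


def binom_upper_tail(inp: BinomialInput) -> float:
    """P(X >= k) for X ~ Binomial(n, p).

    Computed via the regularized incomplete beta function (scipy survival
    function), which is evaluated in log space internally and stays finite
    for n up to 1e6 and beyond.
    """
    if inp.k == 0:
        return 1.0
    return float(stats.binom.sf(inp.k - 1, inp.n, inp.p))


def fisher_one_sided(inp: FisherInput) -> float:
    """One-sided (enrichment) Fisher exact p: sum over j >= x of the
    hypergeometric pmf C(C,j) C(N-C,R-j) / C(N,R)."""
    lo = max(0, inp.C + inp.R - inp.N)
    if inp.x == lo:
        return 1.0
    return float(stats.hypergeom.sf(inp.x - 1, inp.N, inp.C, inp.R))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x (number of (x_i, y_j) pairs with x_i > y_j, ties 1/2)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n = len(x)
    r_x = float(ranks[:n].sum())
    return r_x - n * (n + 1) / 2.0


def _exact_mwu_p(x: np.ndarray, y: np.ndarray, alternative: Alternative) -> float:
    """Exact permutation p-value: enumerate all C(n+m, n) assignments of the
    pooled values to the two groups and compare U statistics."""
    pooled = np.concatenate([x, y])
    n, total = len(x), len(pooled)
    ranks = stats.rankdata(pooled)
    offset = n * (n + 1) / 2.0
    u_obs = float(ranks[:n].sum()) - offset
    us = np.array(
        [sum(ranks[i] for i in comb) - offset
         for comb in itertools.combinations(range(total), n)]
    )
    eps = 1e-9
    p_ge = float(np.mean(us >= u_obs - eps))
    p_le = float(np.mean(us <= u_obs + eps))
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    alternative: Alternative = "two-sided",
) -> tuple[float, float]:
    """Mann-Whitney U test of x against y.

    Returns (U, p) where U counts pairs in which x exceeds y (ties 1/2).
    Exact permutation p for n + m <= EXACT_MWU_MAX_TOTAL (correct under
    ties); otherwise the tie-corrected normal approximation with continuity
    correction. If every pooled value is identical the test is degenerate
    and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return u, 1.0
    if len(pooled) <= EXACT_MWU_MAX_TOTAL:
        return u, _exact_mwu_p(x, y, alternative)
    res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return u, float(res.pvalue)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, returned in the input
    order. NaN entries (untested hypotheses) are passed through and do not
    count toward m.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    adj = np.empty(m)
    adj[order] = q
    out[mask] = adj
    return out


def log_binom_pmf(n: int, k: int, p: float) -> float:
    """log P(X = k) for X ~ Binomial(n, p); used by enumeration helpers."""
    if p == 0.0:
        return 0.0 if k == 0 else -math.inf
    if p == 1.0:
        return 0.0 if k == n else -math.inf
    return (
        math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
        + k * math.log(p) + (n - k) * math.log1p(-p)
    )
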