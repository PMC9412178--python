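"""Exact inference primitives: Fisher's exact test, exact Mann-Whitney U,
and Pearson correlation.

Conventions match the GraphPad-style defaults used throughout the analysis:

* Fisher two-sided p is the point-probability ("sum of less-likely tables")
  method: the sum, over all 2x2 tables with the observed margins, of the
  hypergeometric point probabilities no larger than that of the observed
  table. Point probabilities are compared as exact integers (binomial
  numerators over a common denominator), so the comparison carries no
  floating-point tolerance at all.
* Mann-Whitney two-sided p is the doubled smaller exact tail of the
  permutation distribution of U (half-credit for ties), capped at 1.
  Exact mode enumerates all C(n1+n2, n1) group assignments and is used for
  n1+n2 <= 25; larger samples fall back to the tie-corrected normal
  approximation and are flagged.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "TwoByTwo",
    "fisher_exact_two_sided",
    "mann_whitney_exact_two_sided",
    "MannWhitneyResult",
    "mann_whitney_u",
    "pearson_r",
]


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 contingency table; row 1 = group 1 (pos, neg), row 2 = group 2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("table entries must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")


def fisher_exact_two_sided(table: TwoByTwo | tuple[int, int, int, int]) -> float:
    """Two-sided Fisher exact p for a 2x2 table with fixed margins.

    Degenerate margins (an all-zero row or column) carry no information and
    return p = 1.
    """
    if not isinstance(table, TwoByTwo):
        table = TwoByTwo(*table)
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if min(r1, r2, c1, c2) == 0:
        return 1.0
    # Support of the (1,1) cell given margins; point probability of cell x is
    # comb(r1, x) * comb(r2, c1 - x) / comb(n, c1): compare numerators exactly.
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    numerators = [comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)]
    obs = numerators[a - lo]
    p = sum(w for w in numerators if w <= obs) / comb(n, c1)
    return min(1.0, p)


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float
    exact: bool


def mann_whitney_u(x, y) -> float:
    """U statistic for x against y: #{x_i > y_j} + half-credit for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    gt = (x[:, None] > y[None, :]).sum()
    ties = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(ties)


def mann_whitney_exact_two_sided(x, y, max_exact_n: int = 25) -> MannWhitneyResult:
    """Exact two-sided Mann-Whitney U test.

    p = min(1, 2 * min(P(U* >= U), P(U* <= U))) over all C(n1+n2, n1)
    assignments of the pooled values to the two groups. For pooled sizes
    above ``max_exact_n`` a tie-corrected normal approximation (with
    continuity correction) is used and flagged via ``exact=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    n = n1 + n2
    u_obs = mann_whitney_u(x, y)
    if n > max_exact_n:
        return MannWhitneyResult(u_obs, _mwu_normal_approx(pooled, n1, n2, u_obs), exact=False)

    # U via midranks: U = R1 - n1(n1+1)/2, so enumerate rank-sum assignments.
    ranks = rankdata(pooled)
    offset = n1 * (n1 + 1) / 2.0
    eps = 1e-9
    ge = le = total = 0
    for idx in combinations(range(n), n1):
        u_star = ranks[list(idx)].sum() - offset
        total += 1
        if u_star >= u_obs - eps:
            ge += 1
        if u_star <= u_obs + eps:
            le += 1
    p = min(1.0, 2.0 * min(ge, le) / total)
    return MannWhitneyResult(u_obs, p, exact=True)


def _mwu_normal_approx(pooled: np.ndarray, n1: int, n2: int, u_obs: float) -> float:
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (abs(u_obs - mu) - 0.5) / sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))


def pearson_r(x, y) -> float:
    """Product-moment correlation with pairwise exclusion of missing values.

    Raises on fewer than 3 complete pairs or zero variance (a correlation of
    a constant is undefined, not 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = float(np.sqrt((dx**2).sum()))
    sy = float(np.sqrt((dy**2).sum()))
    if sx == 0 or sy == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float((dx * dy).sum() / (sx * sy))
    return max(-1.0, min(1.0, r))
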