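"""Independent brute-force oracles used to validate the package implementations.

These deliberately avoid the code paths they check: the Ward oracle uses a
memoized top-down recursion over explicit cluster trees, the rank-sum oracle
enumerates label assignments, and the Fisher oracle enumerates hypergeometric
tables from factorials.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


# ---------------------------------------------------------------------------
# Ward clustering (naive O(n^3) re-implementation over explicit cluster trees)


def naive_ward(dist: np.ndarray):
    """Return [(frozenset_of_leaves, height), ...] in merge order.

    Clusters are nested tuples; inter-cluster distances follow the Ward
    minimum-variance recursion evaluated top-down with memoisation.
    """
    n = dist.shape[0]

    def leaves(c):
        if isinstance(c, int):
            return (c,)
        return leaves(c[0]) + leaves(c[1])

    cache: dict[frozenset, float] = {}

    def cdist(c1, c2) -> float:
        key = frozenset((c1, c2))
        if key in cache:
            return cache[key]
        if isinstance(c1, int) and isinstance(c2, int):
            val = float(dist[c1, c2])
        elif not isinstance(c1, int):
            a, b = c1
            na, nb, nk = len(leaves(a)), len(leaves(b)), len(leaves(c2))
            val = (
                (na + nk) * cdist(a, c2)
                + (nb + nk) * cdist(b, c2)
                - nk * cdist(a, b)
            ) / (na + nb + nk)
        else:
            val = cdist(c2, c1)
        cache[key] = val
        return val

    clusters: list = list(range(n))
    merges = []
    while len(clusters) > 1:
        best = None
        for i, j in combinations(range(len(clusters)), 2):
            d = cdist(clusters[i], clusters[j])
            if best is None or d < best[0]:
                best = (d, i, j)
        d, i, j = best
        merged = (clusters[i], clusters[j])
        merges.append((frozenset(leaves(merged)), d))
        clusters = [c for t, c in enumerate(clusters) if t not in (i, j)] + [merged]
        # keep scan order comparable to the row-index order of the iterative
        # implementation: order clusters by smallest contained leaf
        clusters.sort(key=lambda c: min(leaves(c)))
    return merges


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum by full enumeration (no ties)


def enumerate_rank_sum_p(x, y, alternative: str = "two-sided") -> float:
    """Exact rank-sum p by enumerating all label assignments (requires no ties)."""
    x = list(map(float, x))
    y = list(map(float, y))
    combined = sorted(x + y)
    assert len(set(combined)) == len(combined), "oracle requires no ties"
    rank = {v: r for r, v in enumerate(combined, start=1)}
    w_obs = sum(rank[v] for v in x)
    n, n1 = len(combined), len(x)
    all_ranks = list(range(1, n + 1))
    ws = [sum(subset) for subset in combinations(all_ranks, n1)]
    total = len(ws)
    p_le = sum(1 for w in ws if w <= w_obs) / total
    p_ge = sum(1 for w in ws if w >= w_obs) / total
    if alternative == "less":
        return p_le
    if alternative == "greater":
        return p_ge
    return min(1.0, 2.0 * min(p_le, p_ge))


# ---------------------------------------------------------------------------
# Fisher exact by hypergeometric enumeration


def enumerate_fisher_p(table, alternative: str = "two-sided") -> float:
    """Fisher exact p by direct hypergeometric enumeration of all tables
    with the observed margins (probability-mass rule for two-sided)."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, c1 - (c + d)), min(r1, c1)

    def prob(x: int) -> float:
        return comb(r1, x) * comb(n - r1, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    if alternative == "greater":
        return sum(prob(x) for x in range(a, hi + 1))
    if alternative == "less":
        return sum(prob(x) for x in range(lo, a + 1))
    # same relative slack as the standard implementations use for fp safety
    return min(1.0, sum(p for p in (prob(x) for x in range(lo, hi + 1))
                        if p <= p_obs * (1 + 1e-7)))


# ---------------------------------------------------------------------------
# Welch t p-value via the incomplete-beta representation


def welch_p(x, y) -> tuple[float, float]:
    """Welch statistic and two-sided p computed from first principles."""
    from scipy.special import betainc

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx ** 2 / (len(x) - 1) + vy ** 2 / (len(y) - 1))
    p = betainc(df / 2.0, 0.5, df / (df + t ** 2))
    return float(t), float(p)
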