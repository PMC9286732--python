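"""Independent brute-force oracles for the statistical core.

Everything here is written from the textbook definitions with pure-Python
enumeration — no scipy, no statsmodels, no shared code with the package —
so agreement with the implementation is a genuine two-route check.
"""

from __future__ import annotations

import math
from itertools import combinations


def binomial_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Sum of outcome probabilities no larger than the observed one."""
    pk = math.comb(n, k) * p0**k * (1 - p0) ** (n - k)
    total = 0.0
    for i in range(n + 1):
        pi = math.comb(n, i) * p0**i * (1 - p0) ** (n - i)
        if pi <= pk * (1 + 1e-7):
            total += pi
    return min(total, 1.0)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Hypergeometric enumeration of all tables with the observed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x: int) -> float:
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    return min(sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-7)), 1.0)


def bh_adjust(pvals: list[float]) -> list[float]:
    """Naive sorted BH step-up."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        q = min(prev, pvals[idx] * m / rank)
        adj[idx] = q
        prev = q
    return adj


def fisher_combined(pvals: list[float]) -> float:
    """Closed-form chi-square upper tail for even df = 2k."""
    x = -2.0 * sum(math.log(p) for p in pvals)
    k = len(pvals)
    half = x / 2.0
    term, total = 1.0, 1.0
    for i in range(1, k):
        term *= half / i
        total += term
    return min(math.exp(-half) * total, 1.0)


def _midranks(values: list[float]) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def rank_sum_two_sided(x: list[float], y: list[float]) -> float:
    """Full enumeration of group assignments, midrank statistic."""
    pooled = list(x) + list(y)
    ranks = _midranks(pooled)
    n1, n = len(x), len(pooled)
    w_obs = sum(ranks[:n1])
    mu = n1 * (n + 1) / 2.0
    dev = abs(w_obs - mu) - 1e-9
    hits = total = 0
    for idx in combinations(range(n), n1):
        total += 1
        if abs(sum(ranks[i] for i in idx) - mu) >= dev:
            hits += 1
    return hits / total


def ks_d(x: list[float], y: list[float]) -> float:
    """Max ECDF gap by walking the pooled sorted support."""
    best = 0.0
    for v in sorted(set(x) | set(y)):
        fx = sum(1 for u in x if u <= v) / len(x)
        fy = sum(1 for u in y if u <= v) / len(y)
        best = max(best, abs(fx - fy))
    return best


def ks_permutation(x: list[float], y: list[float]) -> tuple[float, float]:
    """Exact permutation two-sample KS by split enumeration."""
    d_obs = ks_d(x, y)
    pooled = list(x) + list(y)
    n1, n = len(x), len(pooled)
    hits = total = 0
    for idx in combinations(range(n), n1):
        chosen = set(idx)
        xs = [pooled[i] for i in chosen]
        ys = [pooled[i] for i in range(n) if i not in chosen]
        total += 1
        if ks_d(xs, ys) >= d_obs - 1e-12:
            hits += 1
    return d_obs, hits / total
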