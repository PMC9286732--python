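"""Statistical core for allele-specific testing.

Standard machinery (exact binomial, Fisher's 2x2, Benjamini-Hochberg,
Fisher's p-value combination, asymptotic KS and rank-sum) is delegated to
scipy/statsmodels.  Two exact small-sample modes are provided in-package
because the scipy exact paths refuse tied data: a permutation two-sample KS
(full enumeration of splits) and an enumeration Wilcoxon rank-sum with
midranks.

Sentinel convention: tests that cannot run (zero totals, empty groups,
under-threshold inputs) return ``math.nan`` rather than raising, so callers
can keep the record with a no-test flag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

NO_TEST = float("nan")

_EXACT_MAX_N = 14          # full split enumeration up to C(14,7) = 3432


# ---------------------------------------------------------------------------
# elementary tests

def binomial_allelic_test(count_a1: int, count_a2: int) -> float:
    """Two-sided exact binomial p-value against an allelic ratio of 0.5."""
    n = count_a1 + count_a2
    if n == 0:
        return NO_TEST
    return float(sps.binomtest(count_a1, n, 0.5).pvalue)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("NaN p-values cannot be adjusted")
    return multipletests(p, method="fdr_bh")[1]


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test; returns (sample odds ratio, p).

    The odds ratio is the unconditional sample estimate ad/bc (inf/nan on
    zero margins), not the conditional MLE.
    """
    table = np.array([[a, b], [c, d]])
    if table.min() < 0:
        raise ValueError("counts must be non-negative")
    odds = (a * d) / (b * c) if b * c > 0 else math.inf if a * d > 0 else math.nan
    p = float(sps.fisher_exact(table, alternative="two-sided")[1])
    return odds, min(p, 1.0)


def fisher_combine(p_values) -> float:
    """Fisher's method: X^2 = -2 sum(ln p) against chi-square with 2k df."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return NO_TEST
    if (p <= 0).any():
        warnings.warn("p-values of 0 clipped for Fisher combination")
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    x2 = -2.0 * np.log(p).sum()
    return float(sps.chi2.sf(x2, 2 * p.size))


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided rank-sum test; exact enumeration (midranks) for small
    samples, tie-corrected normal approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        return NO_TEST
    if x.size + y.size <= _EXACT_MAX_N:
        return _rank_sum_exact(x, y)
    return float(sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)


def _rank_sum_exact(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)          # midranks
    n1, n = x.size, pooled.size
    w_obs = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0               # permutation distribution is
    dev = abs(w_obs - mu) - 1e-9          # symmetric about mu even with ties
    hits = total = 0
    for idx in combinations(range(n), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= dev:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# two-sample KS on weighted positions

def _expand(positions, counts) -> np.ndarray:
    return np.repeat(np.asarray(positions, dtype=float), np.asarray(counts, dtype=int))


def ks_statistic(obs_a: np.ndarray, obs_b: np.ndarray) -> float:
    """Max absolute ECDF difference between two observation vectors."""
    grid = np.unique(np.concatenate([obs_a, obs_b]))
    fa = np.searchsorted(np.sort(obs_a), grid, side="right") / obs_a.size
    fb = np.searchsorted(np.sort(obs_b), grid, side="right") / obs_b.size
    return float(np.abs(fa - fb).max())


def ks_two_sample(
    positions_a,
    counts_a,
    positions_b,
    counts_b,
    min_obs: int = 5,
    method: str = "asymp",
    n_resamples: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-sample KS on weighted positions: (D, p).

    ``method='asymp'`` uses the standard asymptotic two-sample formula,
    which is conservative under heavy ties.  ``'permutation'`` is exact
    under exchangeability, ties included: every split of the pooled
    multiset is enumerated when feasible, otherwise ``n_resamples``
    Monte-Carlo label shuffles (seeded, so deterministic) are used.
    Returns (nan, nan) when either side has fewer than ``min_obs`` reads.
    """
    a = _expand(positions_a, counts_a)
    b = _expand(positions_b, counts_b)
    if a.size < min_obs or b.size < min_obs:
        return NO_TEST, NO_TEST
    d = ks_statistic(a, b)
    if method == "permutation":
        return d, _ks_perm_pvalue(a, b, d, n_resamples, seed)
    res = sps.ks_2samp(a, b, method="asymp")
    return d, float(min(res.pvalue, 1.0))


def _ks_perm_pvalue(a: np.ndarray, b: np.ndarray, d: float, n_resamples: int, seed: int) -> float:
    pooled = np.concatenate([a, b])
    n1, n = a.size, pooled.size
    if n <= 2 * _EXACT_MAX_N and math.comb(n, n1) <= 20000:
        hits = total = 0
        for idx in combinations(range(n), n1):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            total += 1
            if ks_statistic(pooled[mask], pooled[~mask]) >= d - 1e-12:
                hits += 1
        return hits / total
    # Monte-Carlo permutation; +1/+1 correction keeps p > 0
    grid, codes = np.unique(pooled, return_inverse=True)
    k = grid.size
    rng = np.random.default_rng([seed, n, n1])
    hits = 0
    for _ in range(n_resamples):
        perm = rng.permutation(codes)
        ca = np.bincount(perm[:n1], minlength=k) / n1
        cb = np.bincount(perm[n1:], minlength=k) / (n - n1)
        if np.abs(np.cumsum(ca - cb)).max() >= d - 1e-12:
            hits += 1
    return (hits + 1) / (n_resamples + 1)


# ---------------------------------------------------------------------------
# shape-change classification

@dataclass
class ShapeTestResult:
    unit_id: str
    d: float
    p_value: float
    q_value: float = math.nan
    shape_class: str = "none"        # {"single", "multi", "none"}
    masked_pos: int | None = None


def classify_shape_change(
    positions: np.ndarray,
    counts_a1: np.ndarray,
    counts_a2: np.ndarray,
    nominal_threshold: float,
    min_obs: int = 5,
    method: str = "asymp",
) -> tuple[str, int]:
    """Single- vs multi-TSS attribution of a significant shape change.

    The member TSS with the largest absolute allelic count difference is
    masked (5'-most position on ties, positions being in 5'->3' order) and
    the KS test re-run: a residual p above the first-pass nominal threshold
    means one TSS carried the change ("single"), otherwise several did
    ("multi").  If masking starves either allele below ``min_obs``
    observations the change was by construction removable: "single".
    """
    positions = np.asarray(positions)
    diff = np.abs(np.asarray(counts_a1, dtype=int) - np.asarray(counts_a2, dtype=int))
    mask_idx = int(np.argmax(diff))      # argmax takes the first = 5'-most tie
    keep = np.ones(positions.size, dtype=bool)
    keep[mask_idx] = False
    a1 = np.asarray(counts_a1)[keep]
    a2 = np.asarray(counts_a2)[keep]
    pos = positions[keep]
    if a1.sum() < min_obs or a2.sum() < min_obs:
        return "single", int(positions[mask_idx])
    _, p = ks_two_sample(pos, a1, pos, a2, min_obs=min_obs, method=method)
    label = "single" if (math.isnan(p) or p > nominal_threshold) else "multi"
    return label, int(positions[mask_idx])


def nominal_threshold_at_fdr(p_values, fdr: float = 0.10) -> float:
    """Highest nominal p-value accepted at the given BH FDR level."""
    p = np.asarray(p_values, dtype=float)
    q = bh_fdr(p)
    accepted = p[q <= fdr]
    return float(accepted.max()) if accepted.size else 0.0
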