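"""Allelic-imbalance block calling with a three-state HMM, and the
downstream domain / gene-level classification.

Model: at each informative position (>= 1 tagged read) the allele-1 count
out of the tagged total is binomial with success probability 0.5 (balanced
state), rho (allele-1-biased) or 1-rho (allele-2-biased).  The chain starts
balanced (up to the switch probability tau) and switches state with
probability tau per step; Viterbi decoding turns maximal runs of a biased
state into blocks.  This re-implements the published AlleleHMM idea with a
fixed emission parameter, validated on planted truth.

Reciprocal-cross logic: a block biased toward the same *strain* in both
cross directions is a strain effect; toward the same *parent* (so the
strain flips with the cross) it is imprinted.  Cross labels name the mother
first: in "A1xA2" allele 1 is maternal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .stats import binomial_allelic_test, fisher_combine

TAU_GRID_DEFAULT = (1e-5, 1e-4, 1e-3, 1e-2)


@dataclass
class HmmConfig:
    tau: float = 1e-4
    rho: float = 0.9
    tau_grid: tuple[float, ...] = TAU_GRID_DEFAULT

    def __post_init__(self):
        if not 0.0 <= self.tau < 1.0 / 3.0:
            raise ValueError("tau must be in [0, 1/3)")
        if not 0.5 < self.rho < 1.0:
            raise ValueError("rho must be in (0.5, 1)")


@dataclass
class HmmBlock:
    contig: str
    strand: str
    start: int
    end: int                       # half-open, allele-1 coordinates
    direction: str                 # "A1" | "A2" (the biased allele)
    a1: int
    a2: int
    p_value: float = math.nan
    organ: str = ""
    cross: str = ""

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def viterbi_states(a1: np.ndarray, a2: np.ndarray, config: HmmConfig) -> np.ndarray:
    """Most probable state path (0 balanced, 1 A1-biased, 2 A2-biased)."""
    a1 = np.asarray(a1, dtype=np.int64)
    a2 = np.asarray(a2, dtype=np.int64)
    n = a1 + a2
    probs = np.array([0.5, config.rho, 1.0 - config.rho])
    # (T, 3) emission log-likelihoods
    ll = sps.binom.logpmf(a1[:, None], n[:, None], probs[None, :])
    with np.errstate(divide="ignore"):
        log_tau = np.log(config.tau) if config.tau > 0 else -np.inf
        log_stay = np.log(1.0 - 2.0 * config.tau)
        trans = np.full((3, 3), log_tau)
        np.fill_diagonal(trans, log_stay)
        init = np.array([log_stay, log_tau, log_tau])
    T = len(a1)
    delta = init + ll[0]
    back = np.zeros((T, 3), dtype=np.int8)
    for t in range(1, T):
        cand = delta[:, None] + trans          # prev state x next state
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(3)] + ll[t]
    states = np.zeros(T, dtype=np.int8)
    states[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        states[t - 1] = back[t, states[t]]
    return states


def hmm_call_blocks(
    positions: np.ndarray,
    a1: np.ndarray,
    a2: np.ndarray,
    config: HmmConfig,
    contig: str = "",
    strand: str = "+",
) -> list[HmmBlock]:
    """Call allelically biased blocks from sorted informative positions."""
    positions = np.asarray(positions, dtype=np.int64)
    if positions.size < 2:
        return []
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    states = viterbi_states(a1, a2, config)
    blocks: list[HmmBlock] = []
    t = 0
    while t < len(states):
        s = states[t]
        u = t
        while u < len(states) and states[u] == s:
            u += 1
        if s != 0:
            c1 = int(np.sum(a1[t:u]))
            c2 = int(np.sum(a2[t:u]))
            blocks.append(
                HmmBlock(
                    contig=contig,
                    strand=strand,
                    start=int(positions[t]),
                    end=int(positions[u - 1]) + 1,
                    direction="A1" if s == 1 else "A2",
                    a1=c1,
                    a2=c2,
                    p_value=binomial_allelic_test(c1, c2),
                )
            )
        t = u
    return blocks


# ---------------------------------------------------------------------------
# tau selection

def _jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union else 0.0


def select_tau(
    blocks_by_tau: dict[float, list[HmmBlock]],
    reference_units: list[tuple[tuple[int, int], bool]],
) -> float:
    """Pick the tau maximizing sensitivity + specificity of classifying
    reference units (interval, is_allele_specific) by block overlap.
    Ties break toward the smaller tau."""
    if not reference_units:
        raise ValueError("empty reference set")
    best_tau, best_score = None, -np.inf
    for tau in sorted(blocks_by_tau):
        blocks = blocks_by_tau[tau]
        tp = fp = tn = fn = 0
        for (start, end), truth in reference_units:
            hit = any(b.start < end and start < b.end for b in blocks)
            if truth and hit:
                tp += 1
            elif truth:
                fn += 1
            elif hit:
                fp += 1
            else:
                tn += 1
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        if sens + spec > best_score + 1e-12:
            best_tau, best_score = tau, sens + spec
    return float(best_tau)


# ---------------------------------------------------------------------------
# domains

@dataclass
class Domain:
    contig: str
    start: int
    end: int
    domain_class: str              # "strain_effect" | "imprinted"
    direction: str                 # biased strain ("A1"/"A2") or parent ("maternal"/"paternal")
    organs: list[str] = field(default_factory=list)
    p_values: dict[str, float] = field(default_factory=dict)


def _maternal(cross: str) -> str:
    return "A1" if cross == "A1xA2" else "A2"


def merge_blocks_to_domains(
    blocks: list[HmmBlock],
    replicate_pvalues: dict[tuple[str, str, int], list[tuple[tuple[int, int], str, float]]] | None = None,
    alpha: float = 0.05,
) -> list[Domain]:
    """Reciprocal-cross classification and cross-organ merging of blocks.

    ``blocks`` are per organ x cross (pooled replicates; ``organ``/``cross``
    set).  ``replicate_pvalues`` optionally maps (organ, cross, replicate) to
    [(interval, direction, p)] per-replicate evidence at candidate blocks;
    per block the same-direction replicate p-values are Fisher-combined and
    the block kept when the combined p <= alpha.  Blocks biased to the same
    strain in both cross directions make a strain-effect domain; to the same
    parent, an imprinted domain; overlapping same-class domains merge across
    organs.
    """
    crosses = {b.cross for b in blocks}
    if crosses and crosses != {"A1xA2", "A2xA1"}:
        raise ValueError("both reciprocal cross directions are required")

    kept: list[HmmBlock] = []
    for b in blocks:
        if replicate_pvalues is None:
            if not math.isnan(b.p_value) and b.p_value <= alpha:
                kept.append(b)
            continue
        ps = []
        consistent = True
        for (organ, cross, _rep), recs in replicate_pvalues.items():
            if organ != b.organ or cross != b.cross:
                continue
            for (s, e), direction, p in recs:
                if s < b.end and b.start < e:
                    if direction != b.direction:
                        consistent = False
                    else:
                        ps.append(p)
        if consistent and ps and fisher_combine(ps) <= alpha:
            kept.append(b)

    # classify per organ by reciprocal-cross agreement
    candidates: list[Domain] = []
    by_organ: dict[str, dict[str, list[HmmBlock]]] = {}
    for b in kept:
        by_organ.setdefault(b.organ, {}).setdefault(b.cross, []).append(b)
    for organ, per_cross in by_organ.items():
        for b1 in per_cross.get("A1xA2", []):
            for b2 in per_cross.get("A2xA1", []):
                if not (b1.start < b2.end and b2.start < b1.end):
                    continue
                if b1.strand != b2.strand:
                    continue
                start, end = min(b1.start, b2.start), max(b1.end, b2.end)
                if b1.direction == b2.direction:
                    cls, direction = "strain_effect", b1.direction
                else:
                    cls = "imprinted"
                    direction = "maternal" if b1.direction == _maternal(b1.cross) else "paternal"
                candidates.append(
                    Domain(
                        b1.contig, start, end, cls, direction, [organ],
                        {f"{organ}:{b1.cross}": b1.p_value, f"{organ}:{b2.cross}": b2.p_value},
                    )
                )

    # merge overlapping same-class candidates across organs
    candidates.sort(key=lambda d: (d.contig, d.domain_class, d.direction, d.start))
    merged: list[Domain] = []
    for d in candidates:
        last = merged[-1] if merged else None
        if (
            last
            and last.contig == d.contig
            and last.domain_class == d.domain_class
            and last.direction == d.direction
            and d.start <= last.end
        ):
            last.end = max(last.end, d.end)
            last.organs = sorted(set(last.organs) | set(d.organs))
            last.p_values.update(d.p_values)
        else:
            merged.append(
                Domain(d.contig, d.start, d.end, d.domain_class, d.direction,
                       list(d.organs), dict(d.p_values))
            )
    return merged


# ---------------------------------------------------------------------------
# gene-level state and adjacency

def classify_gene_allelic_state(
    counts_by_cross: dict[str, tuple[int, int]],
    q_by_cross: dict[str, float],
    fdr: float = 0.10,
) -> str:
    """Gene state from reciprocal crosses: "strain", "imprinted" or "none".

    ``counts_by_cross`` maps cross -> (a1, a2) pooled gene-body counts;
    ``q_by_cross`` holds the BH-adjusted binomial q per cross (adjusted
    within the caller's per-cross family).
    """
    needed = {"A1xA2", "A2xA1"}
    if set(counts_by_cross) != needed or set(q_by_cross) != needed:
        return "none"
    if any(q_by_cross[c] > fdr or math.isnan(q_by_cross[c]) for c in needed):
        return "none"
    bias = {c: ("A1" if counts_by_cross[c][0] >= counts_by_cross[c][1] else "A2") for c in needed}
    if bias["A1xA2"] == bias["A2xA1"]:
        return "strain"
    return "imprinted"


def adjacency_sharing_test(
    gene_qs: list[tuple[str, float]],
    neighbor_of: dict[str, str],
    fdr_specific: float = 0.10,
    fdr_background: float = 0.90,
) -> tuple[float, float]:
    """Do allele-specific genes cluster next to allele-specific neighbors?

    Focal genes with q <= fdr_specific (allele-specific) or q > fdr_background
    (confidently balanced) enter a 2x2 against whether their nearest neighbor
    is allele-specific; Fisher's exact test.  Returns (odds ratio, p) or
    (nan, nan) when a stratum is empty.
    """
    from .stats import fisher_exact_2x2

    qmap = dict(gene_qs)
    table = np.zeros((2, 2), dtype=int)
    for gene, q in gene_qs:
        if q <= fdr_specific:
            row = 0
        elif q > fdr_background:
            row = 1
        else:
            continue
        nb = neighbor_of.get(gene)
        if nb is None or nb not in qmap:
            continue
        col = 0 if qmap[nb] <= fdr_specific else 1
        table[row, col] += 1
    if table.sum(axis=1).min() == 0:
        return math.nan, math.nan
    return fisher_exact_2x2(*table.ravel())


def count_genes_per_domain(
    domains: list[Domain],
    annotations: list[tuple[str, int, int, str]],
) -> list[int]:
    """Genes per domain after merging overlapping/bookended same-strand
    annotations (contig, start, end, strand) so each cluster counts once."""
    merged: dict[tuple[str, str], list[list[int]]] = {}
    for contig, start, end, strand in sorted(annotations):
        runs = merged.setdefault((contig, strand), [])
        if runs and start <= runs[-1][1]:       # overlap or bookend
            runs[-1][1] = max(runs[-1][1], end)
        else:
            runs.append([start, end])
    out = []
    for d in domains:
        n = 0
        for (contig, _strand), runs in merged.items():
            if contig != d.contig:
                continue
            n += sum(1 for s, e in runs if s < d.end and d.start < e)
        out.append(n)
    return out
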