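"""Allelic termination windows, mRNA structure changes and stability.

An allelic-termination (AT) window marks a 3' region transcribed on one
allele only: it is the intersection of a transcription unit with an
allelic-imbalance block that (1) starts inside the unit, (2) ends in the
final 10% of the unit or beyond it, and (3) covers at most half the unit.
The block's biased allele is the *long allele* (it keeps transcribing).
Downstream, a gene whose mRNA-level imbalance blocks fall between 10 kb
upstream of the AT window and its end is flagged as a primary-structure
change, and per-allele mRNA stability is the exonic mRNA count over the
nascent gene-body count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hmm import HmmBlock
from .stats import fisher_exact_2x2

from scipy import stats as sps


@dataclass(frozen=True)
class TranscriptionUnit:
    contig: str
    start: int
    end: int
    strand: str
    gene_id: str


@dataclass
class ATWindow:
    unit: TranscriptionUnit
    start: int
    end: int
    long_allele: str

    @property
    def length(self) -> int:
        return self.end - self.start

    def check_rules(self, final_fraction: float = 0.10, length_cap: float = 0.50) -> bool:
        """All three AT rules, assertable per record: the window lies inside
        its unit, covers at most ``length_cap`` of it, and its strand-aware
        3' edge reaches the final ``final_fraction`` of the unit."""
        u = self.unit
        ulen = u.end - u.start
        if not (u.start <= self.start < self.end <= u.end):
            return False
        if self.length > length_cap * ulen:
            return False
        if u.strand == "+":
            return self.end >= u.end - final_fraction * ulen
        return self.start <= u.start + final_fraction * ulen


def call_at_windows(
    units: list[TranscriptionUnit],
    blocks: list[HmmBlock],
    final_fraction: float = 0.10,
    length_cap: float = 0.50,
) -> list[ATWindow]:
    """Intersect units with same-strand blocks under the three AT rules.

    Multiple qualifying blocks for one unit merge into a single window
    spanning the union of their qualifying intersections.
    """
    out: list[ATWindow] = []
    for u in units:
        ulen = u.end - u.start
        if u.strand == "+":
            tail_lo = u.end - final_fraction * ulen
        else:
            tail_hi = u.start + final_fraction * ulen
        span: list[int] | None = None
        allele = None
        for b in blocks:
            if b.contig != u.contig or b.strand != u.strand:
                continue
            if u.strand == "+":
                starts_inside = u.start <= b.start < u.end
                ends_in_tail = b.end >= tail_lo
            else:
                starts_inside = u.start < b.end <= u.end
                ends_in_tail = b.start <= tail_hi
            if not (starts_inside and ends_in_tail):
                continue
            s, e = max(u.start, b.start), min(u.end, b.end)
            if e - s > length_cap * ulen:
                continue
            if span is None:
                span, allele = [s, e], b.direction
            elif b.direction == allele:
                span = [min(span[0], s), max(span[1], e)]
        if span is not None and span[1] - span[0] <= length_cap * ulen:
            out.append(ATWindow(u, span[0], span[1], allele))
    return out


def flag_mrna_structure_change(
    windows: list[ATWindow],
    mrna_blocks: list[HmmBlock],
    upstream: int = 10_000,
) -> list[bool]:
    """True when any mRNA-level imbalance block intersects the strand-aware
    interval from 10 kb upstream of the AT window to its end."""
    flags = []
    for w in windows:
        if w.unit.strand == "+":
            lo, hi = w.start - upstream, w.end
        else:
            lo, hi = w.start, w.end + upstream
        hit = any(
            b.contig == w.unit.contig and b.start < hi and lo < b.end
            for b in mrna_blocks
        )
        flags.append(hit)
    return flags


@dataclass
class StabilityRecord:
    gene_id: str
    mrna: dict[str, int]
    nascent: dict[str, int]
    stability: dict[str, float]
    allelic_difference: float       # |log2(stab_A1 / stab_A2)|
    usable: bool


def stability_index(
    mrna_counts: dict[str, tuple[int, int]],
    nascent_counts: dict[str, tuple[int, int]],
    min_reads: int = 10,
) -> list[StabilityRecord]:
    """Per-gene allelic stability = exonic mRNA / nascent gene-body reads.

    Genes with fewer than ``min_reads`` allele-specific nascent reads on
    either allele are dropped; zero-mRNA alleles yield stability 0 and an
    unusable log-ratio (kept, flagged).
    """
    out = []
    for gene, (n1, n2) in nascent_counts.items():
        if n1 < min_reads or n2 < min_reads:
            continue
        m1, m2 = mrna_counts.get(gene, (0, 0))
        s1, s2 = m1 / n1, m2 / n2
        usable = s1 > 0 and s2 > 0
        diff = abs(math.log2(s1 / s2)) if usable else math.nan
        out.append(
            StabilityRecord(
                gene_id=gene,
                mrna={"A1": m1, "A2": m2},
                nascent={"A1": n1, "A2": n2},
                stability={"A1": s1, "A2": s2},
                allelic_difference=diff,
                usable=usable,
            )
        )
    return out


def group_comparisons(
    windows: list[ATWindow],
    flags: list[bool],
    stability: list[StabilityRecord],
    all_genes: list[str],
    adjacent_bias: list[tuple[str, str]] | None = None,
) -> dict:
    """The three group-level tests.

    (a) Fisher: structure-change flag x having an AT window, over all genes;
    (b) one-sided KS: allelic stability difference of flagged vs unflagged
        AT-window genes (flagged expected larger);
    (c) Fisher: does the neighbor's high-expression allele match the host's
        early-terminating (short) allele?  ``adjacent_bias`` lists
        (early_termination_allele, neighbor_high_allele) pairs.
    """
    flagged_genes = {w.unit.gene_id for w, f in zip(windows, flags) if f}
    window_genes = {w.unit.gene_id for w in windows}
    a = len(flagged_genes)
    b = len(window_genes) - a
    other = [g for g in all_genes if g not in window_genes]
    # mRNA structure changes outside AT windows are not called here, so the
    # enrichment uses flagged-in-window vs all remaining genes
    c, d = 0, len(other)
    fisher_structure = fisher_exact_2x2(a, b, c, d) if d else (math.nan, math.nan)

    diffs_flagged = [
        r.allelic_difference for r in stability if r.usable and r.gene_id in flagged_genes
    ]
    diffs_unflagged = [
        r.allelic_difference
        for r in stability
        if r.usable and r.gene_id in window_genes and r.gene_id not in flagged_genes
    ]
    if diffs_flagged and diffs_unflagged:
        # one-sided: flagged genes stochastically larger differences
        # (scipy's "less" = CDF of the first sample lies below the second)
        ks = sps.ks_2samp(diffs_flagged, diffs_unflagged, alternative="less")
        ks_result = (float(ks.statistic), float(ks.pvalue))
    else:
        ks_result = (math.nan, math.nan)

    if adjacent_bias:
        a = sum(1 for e, nb in adjacent_bias if e == "A1" and nb == "A1")
        b2 = sum(1 for e, nb in adjacent_bias if e == "A1" and nb == "A2")
        c2 = sum(1 for e, nb in adjacent_bias if e == "A2" and nb == "A1")
        d2 = sum(1 for e, nb in adjacent_bias if e == "A2" and nb == "A2")
        fisher_adj = fisher_exact_2x2(a, b2, c2, d2)
    else:
        fisher_adj = (math.nan, math.nan)

    return {
        "structure_fisher": fisher_structure,
        "stability_ks_one_sided": ks_result,
        "n_flagged": len(diffs_flagged),
        "n_unflagged": len(diffs_unflagged),
        "adjacency_fisher": fisher_adj,
    }
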