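"""End-to-end glue: from read tables to called objects and test tables.

These helpers chain the module-level operations in the order the analyses
expect (count -> call -> cluster -> test), so the command-line layer, the
test-suite and reproduction scripts all execute the identical path.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .hmm import HmmBlock, HmmConfig, hmm_call_blocks
from .sim.generate import TruthSet
from .sim.plan import downstream
from .stats import (
    ShapeTestResult,
    bh_fdr,
    binomial_allelic_test,
    classify_shape_change,
    ks_two_sample,
    nominal_threshold_at_fdr,
)
from .tss import (
    CandidateRegion,
    PausePair,
    SiteCounts,
    Tsc,
    call_max_pause,
    call_tss,
    cluster_tsc,
    make_base_counts,
    pair_tss_pause,
)


def candidate_regions_from_truth(truth: TruthSet, pad: int = 80) -> list[CandidateRegion]:
    """One candidate regulatory region per planted locus, covering its TSSs
    and pause window (what a run-on-based regulatory-element caller would
    report around an active promoter)."""
    regions = []
    for locus in truth.loci:
        lo = min(downstream(locus.max_tss.pos_a1, -pad // 2, locus.strand),
                 downstream(locus.max_tss.pos_a1, pad, locus.strand))
        hi = max(downstream(locus.max_tss.pos_a1, -pad // 2, locus.strand),
                 downstream(locus.max_tss.pos_a1, pad, locus.strand))
        regions.append(CandidateRegion(locus.contig, lo, hi + 1, locus.gene_id))
    return regions


def region_strands(truth: TruthSet) -> dict[str, str]:
    return {locus.gene_id: locus.strand for locus in truth.loci}


def call_tscs(
    reads: pd.DataFrame,
    regions: list[CandidateRegion],
    cfg: AnalysisConfig | None = None,
) -> tuple[SiteCounts, list[Tsc]]:
    cfg = cfg or AnalysisConfig()
    counts5 = make_base_counts(reads, "five_prime")
    tss = call_tss(counts5, regions, cfg.min_tss_reads)
    return counts5, cluster_tsc(tss, cfg.tsc_merge_gap)


def abundance_table(tscs: list[Tsc], cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Per-TSC allelic abundance: exact binomial on summed tagged counts,
    BH within the family."""
    cfg = cfg or AnalysisConfig()
    rows = []
    for t in tscs:
        a1 = int(t.members["A1"].sum())
        a2 = int(t.members["A2"].sum())
        rows.append(
            {
                "tsc_id": t.tsc_id,
                "region_id": t.region_id,
                "a1": a1,
                "a2": a2,
                "p": binomial_allelic_test(a1, a2),
            }
        )
    df = pd.DataFrame(rows, columns=["tsc_id", "region_id", "a1", "a2", "p"])
    tested = df["p"].notna()
    df["q"] = np.nan
    if tested.any():
        df.loc[tested, "q"] = bh_fdr(df.loc[tested, "p"].to_numpy())
    df["significant"] = df["q"] <= cfg.fdr_abundance
    return df


def shape_analysis(
    tscs: list[Tsc],
    cfg: AnalysisConfig | None = None,
    min_obs: int = 5,
    method: str = "permutation",
) -> list[ShapeTestResult]:
    """Allelic initiation-shape testing with single/multi classification.

    First pass: two-sample KS of the allelic 5'-end distributions of every
    TSC with >= 5 tagged reads per allele; BH at the discovery FDR.  Second
    pass on significant TSCs: mask the member with the largest allelic
    difference and re-test against the highest nominal first-pass p-value
    that survived the FDR.
    """
    cfg = cfg or AnalysisConfig()
    results: list[ShapeTestResult] = []
    tested: list[tuple[ShapeTestResult, Tsc]] = []
    for t in tscs:
        pos = t.members["pos"].to_numpy()
        a1 = t.members["A1"].to_numpy()
        a2 = t.members["A2"].to_numpy()
        d, p = ks_two_sample(pos, a1, pos, a2, min_obs=min_obs, method=method)
        r = ShapeTestResult(unit_id=t.tsc_id, d=d, p_value=p)
        results.append(r)
        if not math.isnan(p):
            tested.append((r, t))
    if not tested:
        return results
    ps = [r.p_value for r, _ in tested]
    qs = bh_fdr(ps)
    threshold = nominal_threshold_at_fdr(ps, cfg.fdr_abundance)
    for (r, t), q in zip(tested, qs):
        r.q_value = float(q)
        if q <= cfg.fdr_abundance:
            pos = t.members["pos"].to_numpy()
            order = np.argsort(pos) if t.strand == "+" else np.argsort(-pos)
            label, masked = classify_shape_change(
                pos[order],
                t.members["A1"].to_numpy()[order],
                t.members["A2"].to_numpy()[order],
                threshold,
                min_obs=min_obs,
                method=method,
            )
            r.shape_class, r.masked_pos = label, masked
    return results


def pause_pairs(
    reads: pd.DataFrame,
    regions: list[CandidateRegion],
    strands: dict[str, str],
    cfg: AnalysisConfig | None = None,
) -> tuple[list[PausePair], dict[str, tuple[int, int]]]:
    """Allelic maxTSS/maxPause pairs per candidate region plus per-region
    allelic 3'-end read totals."""
    cfg = cfg or AnalysisConfig()
    counts5 = make_base_counts(reads, "five_prime")
    counts3 = make_base_counts(reads, "three_prime")
    pairs: list[PausePair] = []
    totals: dict[str, tuple[int, int]] = {}
    for reg in regions:
        strand = strands[reg.region_id]
        sub5 = counts5.in_region(reg.contig, reg.start, reg.end, strand)
        max_tss = {}
        for allele in ("A1", "A2"):
            if sub5[allele].sum() < cfg.pause_min_allelic_reads:
                max_tss = {}
                break
            top = sub5[allele].max()
            ties = sub5.loc[sub5[allele] == top, "pos"]
            max_tss[allele] = int(ties.min() if strand == "+" else ties.max())
        if not max_tss:
            continue
        max_pause = {
            allele: call_max_pause(counts3, reg, allele, strand, cfg.pause_min_allelic_reads)
            for allele in ("A1", "A2")
        }
        sub3 = counts3.in_region(reg.contig, reg.start, reg.end, strand)
        totals[reg.region_id] = (int(sub3["A1"].sum()), int(sub3["A2"].sum()))
        pairs.append(
            pair_tss_pause(reg.region_id, strand, max_tss, max_pause, cfg.pause_pair_window)
        )
    return pairs, totals


def informative_positions(
    reads: pd.DataFrame,
    organ: str,
    cross: str,
    end: str = "three_prime",
) -> dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Pooled-replicate allele-tagged counts per covered base, per
    (contig, strand), the HMM's emission input."""
    sub = reads[(reads["organ"] == organ) & (reads["cross"] == cross) & (reads["allele"] != "untagged")]
    out = {}
    for (contig, strand), grp in sub.groupby(["contig", "strand"], observed=True):
        counts = (
            grp.groupby([end, "allele"], observed=True)
            .size()
            .unstack("allele", fill_value=0)
            .reindex(columns=["A1", "A2"], fill_value=0)
            .sort_index()
        )
        out[(contig, strand)] = (
            counts.index.to_numpy(dtype=np.int64),
            counts["A1"].to_numpy(),
            counts["A2"].to_numpy(),
        )
    return out


def call_blocks_all(
    reads: pd.DataFrame,
    hmm_cfg: HmmConfig,
    organs: tuple[str, ...],
    crosses: tuple[str, ...] = ("A1xA2", "A2xA1"),
) -> list[HmmBlock]:
    blocks: list[HmmBlock] = []
    for organ in organs:
        for cross in crosses:
            for (contig, strand), (pos, a1, a2) in informative_positions(reads, organ, cross).items():
                for b in hmm_call_blocks(pos, a1, a2, hmm_cfg, contig, strand):
                    b.organ, b.cross = organ, cross
                    blocks.append(b)
    return blocks


def gene_states(
    body_counts: pd.DataFrame, cfg: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Per-gene strain/imprinted/none calls from reciprocal crosses."""
    from .hmm import classify_gene_allelic_state

    cfg = cfg or AnalysisConfig()
    pooled = (
        body_counts.groupby(["gene", "cross"], observed=True)[["A1", "A2"]].sum().reset_index()
    )
    pooled["p"] = [
        binomial_allelic_test(int(r.A1), int(r.A2)) for r in pooled.itertuples()
    ]
    pooled["q"] = np.nan
    for cross, grp in pooled.groupby("cross", observed=True):
        tested = grp["p"].notna()
        if tested.any():
            pooled.loc[grp.index[tested], "q"] = bh_fdr(grp.loc[tested, "p"].to_numpy())
    rows = []
    for gene, grp in pooled.groupby("gene", observed=True):
        counts = {r.cross: (int(r.A1), int(r.A2)) for r in grp.itertuples()}
        qs = {r.cross: (float(r.q) if not pd.isna(r.q) else math.nan) for r in grp.itertuples()}
        state = classify_gene_allelic_state(counts, qs, cfg.fdr_abundance)
        rows.append({"gene": gene, "state": state, **{f"q_{c}": qs.get(c) for c in ("A1xA2", "A2xA1")}})
    return pd.DataFrame(rows)
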