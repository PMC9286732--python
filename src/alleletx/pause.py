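"""Dissection of promoter-proximal pause position determinants.

Pol II pauses 20-60 bp downstream of the TSS, preferentially on a C
immediately after a G-rich stretch.  Where the two alleles pause at
different distances from a shared maxTSS, the allele with the smaller
TSS->pause distance is the *short allele*.  These analyses ask what DNA
changes move the pause: SNPs at the active site, in the transcription
bubble (-10..-1) or just downstream (+1..+10), and indels between the TSS
and the pause (which shift a TSS-anchored pause by their full length once
projected onto a common coordinate system).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sim.genome import GenomePair
from .sim.generate import oriented_window
from .sim.plan import downstream
from .stats import ShapeTestResult, bh_fdr, fisher_exact_2x2, ks_two_sample
from .tss import CandidateRegion, PausePair, SiteCounts

EXPLANATIONS = (
    "active_site_snp",
    "bubble_snp",
    "downstream_snp",
    "indel_tss_to_pause",
    "multiple",
    "unexplained",
)


# ---------------------------------------------------------------------------
# allelic pause-shape testing

def pause_shape_test(
    counts: SiteCounts,
    regions: list[CandidateRegion],
    strand_by_region: dict[str, str],
    min_reads: int = 5,
    fdr: float = 0.10,
    control_fdr: float = 0.90,
) -> list[ShapeTestResult]:
    """KS test of allelic 3'-end distributions per candidate region.

    Regions with fewer than ``min_reads`` tagged reads on either allele are
    skipped.  Results carry BH q-values; callers split them into the
    significant set (q <= fdr) and the confident-control set (q > control_fdr).
    """
    if counts.end_type != "three_prime":
        raise ValueError("pause shape testing requires 3'-end counts")
    results: list[ShapeTestResult] = []
    for i, reg in enumerate(regions):
        rid = reg.region_id or f"region_{i:05d}"
        sub = counts.in_region(reg.contig, reg.start, reg.end, strand_by_region.get(rid))
        if sub["A1"].sum() < min_reads or sub["A2"].sum() < min_reads:
            continue
        d, p = ks_two_sample(sub["pos"], sub["A1"], sub["pos"], sub["A2"], min_obs=min_reads)
        results.append(ShapeTestResult(unit_id=rid, d=d, p_value=p))
    if results:
        qs = bh_fdr([r.p_value for r in results])
        for r, q in zip(results, qs):
            r.q_value = float(q)
            r.shape_class = "changed" if q <= fdr else ("control" if q > control_fdr else "none")
    return results


def same_tss_diff_pause_sets(
    pairs: list[PausePair],
    shape_results: list[ShapeTestResult],
    allelic_reads: dict[str, tuple[int, int]],
    min_allelic_reads: int = 5,
    ratio_bounds: tuple[float, float] = (0.5, 2.0),
    fdr: float = 0.10,
    control_fdr: float = 0.90,
) -> tuple[list[PausePair], list[PausePair]]:
    """Split valid pause pairs sharing the maxTSS into the allelic-pause
    test set and the matched control set.

    Test: KS q <= fdr and allelic maxPause positions differ.  Control:
    KS q > control_fdr and identical maxPause.  Both require >= 5 allelic
    reads per allele and an allelic read ratio within ``ratio_bounds``.
    """
    qmap = {r.unit_id: r.q_value for r in shape_results}
    lo, hi = ratio_bounds
    test, control = [], []
    for pair in pairs:
        if not pair.valid or pair.max_tss["A1"] != pair.max_tss["A2"]:
            continue
        q = qmap.get(pair.region_id)
        if q is None or math.isnan(q):
            continue
        a1, a2 = allelic_reads.get(pair.region_id, (0, 0))
        if a1 < min_allelic_reads or a2 < min_allelic_reads:
            continue
        ratio = a1 / a2 if a2 else math.inf
        if not lo <= ratio <= hi:
            continue
        same_pause = pair.max_pause["A1"] == pair.max_pause["A2"]
        if q <= fdr and not same_pause:
            test.append(pair)
        elif q > control_fdr and same_pause:
            control.append(pair)
    return test, control


# ---------------------------------------------------------------------------
# short/long allele bookkeeping

@dataclass
class PauseDeterminantRecord:
    pair: PausePair
    short_allele: str
    long_allele: str
    pause_diff: float                      # |allele-1-projected difference|
    indel_length: int = 0                  # signed: + means short-allele deletion
    tags: list[str] = field(default_factory=list)

    @property
    def explanation(self) -> str:
        real = [t for t in self.tags if t != "multiple"]
        if not real:
            return "unexplained"
        if len(real) > 1:
            return "multiple"
        return real[0]


def _short_long(pair: PausePair) -> tuple[str, str]:
    return ("A1", "A2") if pair.distance["A1"] < pair.distance["A2"] else ("A2", "A1")


def projected_pause_diff(pair: PausePair, genome: GenomePair) -> float:
    """Distance between the allelic maxPause positions after projecting the
    allele-2 pause onto allele-1 coordinates."""
    p1 = pair.max_pause["A1"]
    p2 = genome.a2_to_a1(genome.a1_to_a2(pair.max_pause["A2"]))
    # pause positions are stored on allele-1-projected coordinates already;
    # the round trip guards against anchors inside indel footprints
    return float(abs(p1 - pair.max_pause["A2"])) if p2 == pair.max_pause["A2"] else float(abs(p1 - p2))


def indel_offset_analysis(
    test: list[PausePair],
    control: list[PausePair],
    genome: GenomePair,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Signed indel lengths between the maxTSS and the long-allele pause vs
    the projected allelic pause difference, plus a Fisher enrichment test of
    indel presence (test vs control)."""
    rows = []
    for group, pairs in (("test", test), ("control", control)):
        for pair in pairs:
            short, _long = _short_long(pair)
            length = _indel_between(pair, genome)
            rows.append(
                {
                    "region_id": pair.region_id,
                    "group": group,
                    "short_allele": short,
                    "indel_length": length,
                    "pause_diff": projected_pause_diff(pair, genome),
                }
            )
    df = pd.DataFrame(rows, columns=["region_id", "group", "short_allele", "indel_length", "pause_diff"])
    t_with = int(((df["group"] == "test") & (df["indel_length"] != 0)).sum())
    t_without = int((df["group"] == "test").sum()) - t_with
    c_with = int(((df["group"] == "control") & (df["indel_length"] != 0)).sum())
    c_without = int((df["group"] == "control").sum()) - c_with
    enrich = fisher_exact_2x2(t_with, t_without, c_with, c_without)
    return df, enrich


def _indel_between(pair: PausePair, genome: GenomePair) -> int:
    """Signed length of the first indel between the shared maxTSS and the
    long-allele pause (allele-1 coordinates); positive = deletion on the
    short allele relative to the long allele."""
    short, long_ = _short_long(pair)
    tss = pair.max_tss["A1"]
    pause = pair.max_pause[long_]
    lo, hi = (tss, pause) if pair.strand == "+" else (pause, tss)
    for v in genome.variants:
        if v.kind == "snp":
            continue
        if lo <= v.position <= hi:
            # deletion variant removes sequence from allele 2
            deleted_on = "A2" if v.kind == "deletion" else "A1"
            sign = 1 if deleted_on == short else -1
            return sign * v.indel_length
    return 0


def pause_snp_profile(
    test: list[PausePair],
    control: list[PausePair],
    genome: GenomePair,
    window: int = 20,
    profile_bin: int = 1,
    test_bin: int = 10,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """SNP density around the *short-allele* pause, test vs control."""
    from .initiation import snp_positional_profile

    def anchors(pairs):
        out = []
        for pair in pairs:
            short, _ = _short_long(pair)
            out.append((pair.max_pause[short], pair.strand))
        return out

    return snp_positional_profile(
        anchors(test), anchors(control), genome,
        window=window, profile_bin=profile_bin, test_bin=test_bin, fdr=fdr,
    )


# ---------------------------------------------------------------------------
# pause sequence context

def pause_sequence_context(
    pause_sites: list[tuple[int, str]],
    genome: GenomePair,
    blocks: tuple[tuple[int, int], ...] = ((-20, -11), (-10, -1), (1, 10)),
    logo_window: int = 20,
) -> dict:
    """Base context of pooled unique pause sites on allele 1.

    Per site, G content of the three blocks relative to the pause base
    (block 1 = -20..-11, block 2 = -10..-1, block 3 = +1..+10); paired
    rank-sum comparisons of block 2 against blocks 1 and 3; per-offset base
    frequencies for logo construction.  Duplicate sites must be removed by
    the caller; sites too close to the contig edge are dropped.
    """
    seq = genome.seq1
    base_idx = {b: i for i, b in enumerate("ACGT")}
    g_content = {i: [] for i in range(len(blocks))}
    freq = np.zeros((2 * logo_window + 1, 4))
    pause_base: list[str] = []
    n = 0
    for pos, strand in pause_sites:
        if pos - logo_window < 0 or pos + logo_window >= len(seq):
            continue
        ctx = oriented_window(seq, pos, -logo_window, logo_window, strand)
        n += 1
        pause_base.append(ctx[logo_window])
        for k, b in enumerate(ctx):
            freq[k, base_idx[b]] += 1
        for i, (lo, hi) in enumerate(blocks):
            sub = ctx[logo_window + lo : logo_window + hi + 1]
            g_content[i].append(sub.count("G") / len(sub))
    if n == 0:
        raise ValueError("no usable pause sites")
    freq /= n
    comparisons = {
        "block2_vs_block1": _paired_wilcoxon(g_content[1], g_content[0]),
        "block2_vs_block3": _paired_wilcoxon(g_content[1], g_content[2]),
    }
    counts = pd.Series(pause_base).value_counts()
    return {
        "n_sites": n,
        "freq": freq,
        "offsets": np.arange(-logo_window, logo_window + 1),
        "g_content": {f"block{i+1}": np.array(v) for i, v in g_content.items()},
        "comparisons": comparisons,
        "modal_pause_base": counts.idxmax(),
        "pause_base_counts": counts.to_dict(),
    }


def _paired_wilcoxon(x, y) -> float:
    """Two-sided paired (signed-rank) Wilcoxon; nan when all pairs tie."""
    from scipy import stats as sps

    diff = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if np.all(diff == 0):
        return math.nan
    return float(sps.wilcoxon(diff).pvalue)


# ---------------------------------------------------------------------------
# explanation accounting

def classify_pause_explanations(
    test: list[PausePair],
    genome: GenomePair,
    windows: dict[str, tuple[int, int]] | None = None,
) -> tuple[list[PauseDeterminantRecord], dict[str, float]]:
    """Tag each allelic-pause pair by the variant classes around the
    short-allele pause and report category fractions (exclusive categories;
    >1 class -> "multiple")."""
    windows = windows or {"bubble_snp": (-10, -1), "downstream_snp": (1, 10)}
    snp_positions = {v.position for v in genome.variants if v.kind == "snp"}
    records: list[PauseDeterminantRecord] = []
    for pair in test:
        short, long_ = _short_long(pair)
        anchor = pair.max_pause[short]
        tags = []
        if anchor in snp_positions:
            tags.append("active_site_snp")
        for tag, (lo, hi) in windows.items():
            hit = any(
                downstream(anchor, off, pair.strand) in snp_positions
                for off in range(lo, hi + 1)
                if off != 0
            )
            if hit:
                tags.append(tag)
        length = _indel_between(pair, genome)
        if length != 0:
            tags.append("indel_tss_to_pause")
        records.append(
            PauseDeterminantRecord(
                pair=pair,
                short_allele=short,
                long_allele=long_,
                pause_diff=projected_pause_diff(pair, genome),
                indel_length=length,
                tags=tags,
            )
        )
    fractions = {cat: 0.0 for cat in EXPLANATIONS}
    for r in records:
        fractions[r.explanation] += 1
    total = max(len(records), 1)
    fractions = {k: v / total for k, v in fractions.items()}
    fractions["explained"] = 1.0 - fractions["unexplained"]
    return records, fractions


def pause_distance_comparisons(
    records: list[PauseDeterminantRecord],
    subset_tags: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Two-sample KS of projected pause-difference distributions for each
    tagged subset against its complement."""
    subset_tags = subset_tags or {
        "c_snp": "active_site_snp",
        "indel": "indel_tss_to_pause",
    }
    rows = []
    for name, tag in subset_tags.items():
        inside = [r.pause_diff for r in records if tag in r.tags]
        outside = [r.pause_diff for r in records if tag not in r.tags]
        if not inside or not outside:
            rows.append({"subset": name, "n": len(inside), "median": math.nan,
                         "median_rest": math.nan, "d": math.nan, "p": math.nan})
            continue
        d, p = ks_two_sample(inside, np.ones(len(inside), dtype=int),
                             outside, np.ones(len(outside), dtype=int), min_obs=1)
        rows.append(
            {
                "subset": name,
                "n": len(inside),
                "median": float(np.median(inside)),
                "median_rest": float(np.median(outside)),
                "d": d,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
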