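"""DNA-sequence determinants of transcription initiation.

Four analyses around the maxTSS of each start cluster, all strand-aware and
all using an ascertainment-matched control set (clusters confidently free
of allelic change) rather than genome-wide expectation:

* initiator hierarchy — at maxTSSs whose (-1, 0) dinucleotide differs
  between alleles, the allelic read ratio ordered by the canonical
  preference CA > TA > TG > CG;
* SNP positional profiles — mean SNP density around the maxTSS in test vs
  control sites, Fisher-tested in merged bins;
* base composition / AT content — per-position base-frequency difference
  between the high- and low-use allele, AT fraction in 5 bp windows with
  the initiator positions (-1, 0) masked, and AT->GC SNP enrichment;
* TATA association — PWM log-odds score difference in the -35..-20 window
  against the allelic usage difference;
* shooting gallery — whether initiation lost from a damaged CA initiator
  reappears at nearby candidate initiators (YR dinucleotides) within a
  +/-20 bp window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sim.genome import GenomePair
from .sim.generate import oriented_window
from .sim.plan import downstream
from .stats import bh_fdr, fisher_exact_2x2, wilcoxon_rank_sum

INITIATOR_ORDER = ("CA", "TA", "TG", "CG")
YR = set(INITIATOR_ORDER)


@dataclass(frozen=True)
class MaxTssSite:
    """One maxTSS with allele-1 genomic position and allelic 5' counts."""

    pos: int
    strand: str
    count_a1: int
    count_a2: int
    site_id: str = ""

    @property
    def high_allele(self) -> str | None:
        if self.count_a1 == self.count_a2:
            return None
        return "A1" if self.count_a1 > self.count_a2 else "A2"


def initiator_dinuc(genome: GenomePair, pos: int, strand: str, allele: str) -> str:
    """Transcribed-strand dinucleotide at offsets (-1, 0) of a TSS."""
    local = pos if allele == "A1" else genome.a1_to_a2(pos)
    return oriented_window(genome.seq(allele), local, -1, 0, strand)


# ---------------------------------------------------------------------------
# initiator hierarchy

def dinucleotide_hierarchy(
    sites: list[MaxTssSite], genome: GenomePair
) -> tuple[dict[str, list[float]], pd.DataFrame]:
    """Allelic log2 ratios per initiator-change category, plus pairwise
    rank-sum comparisons (BH-adjusted).

    Category "X>Y" collects maxTSSs where one allele carries the stronger
    initiator X and the other carries Y; the ratio is log2(reads on the
    X-bearing allele / reads on the Y-bearing allele).
    """
    rank = {d: i for i, d in enumerate(INITIATOR_ORDER)}
    ratios: dict[str, list[float]] = {}
    for s in sites:
        d1 = initiator_dinuc(genome, s.pos, s.strand, "A1")
        d2 = initiator_dinuc(genome, s.pos, s.strand, "A2")
        if d1 == d2 or d1 not in YR or d2 not in YR:
            continue
        if s.count_a1 == 0 or s.count_a2 == 0:
            continue
        if rank[d1] < rank[d2]:
            strong, weak, ratio = d1, d2, math.log2(s.count_a1 / s.count_a2)
        else:
            strong, weak, ratio = d2, d1, math.log2(s.count_a2 / s.count_a1)
        ratios.setdefault(f"{strong}>{weak}", []).append(ratio)

    rows = []
    cats = sorted(ratios)
    for ca, cb in combinations(cats, 2):
        rows.append({"a": ca, "b": cb, "p": wilcoxon_rank_sum(ratios[ca], ratios[cb])})
    table = pd.DataFrame(rows, columns=["a", "b", "p"])
    if len(table):
        table["q"] = bh_fdr(table["p"].to_numpy())
    return ratios, table


# ---------------------------------------------------------------------------
# SNP positional profiles

def _snp_offsets(genome: GenomePair, pos: int, strand: str, window: int) -> np.ndarray:
    """Strand-aware offsets of SNPs within +/-window of an anchor."""
    offs = []
    for v in genome.variants:
        if v.kind != "snp":
            continue
        d = v.position - pos if strand == "+" else pos - v.position
        if -window <= d <= window:
            offs.append(d)
    return np.asarray(offs, dtype=int)


def snp_positional_profile(
    test_anchors: list[tuple[int, str]],
    control_anchors: list[tuple[int, str]],
    genome: GenomePair,
    window: int = 100,
    profile_bin: int = 5,
    test_bin: int = 10,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Mean SNP count per ``profile_bin`` around each anchor for test and
    control sets, with a Fisher enrichment test per merged ``test_bin``.

    Returns one row per profile bin with columns mean_test, mean_control,
    and (constant within each merged bin) fisher p/q and a significance flag.
    """
    if not control_anchors:
        raise ValueError("control set is empty")
    edges = np.arange(-window, window + profile_bin, profile_bin)

    def per_site(anchors):
        hits = np.zeros((len(anchors), len(edges) - 1))
        for i, (pos, strand) in enumerate(anchors):
            offs = _snp_offsets(genome, pos, strand, window)
            if offs.size:
                idx = np.clip(np.searchsorted(edges, offs, side="right") - 1, 0, len(edges) - 2)
                np.add.at(hits[i], idx, 1)
        return hits

    h_test, h_ctrl = per_site(test_anchors), per_site(control_anchors)
    df = pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_end": edges[1:],
            "mean_test": h_test.mean(axis=0) if len(h_test) else 0.0,
            "mean_control": h_ctrl.mean(axis=0),
        }
    )
    merge = test_bin // profile_bin
    ps, groups = [], []
    for g in range(0, len(df), merge):
        cols = slice(g, min(g + merge, len(df)))
        t_with = int((h_test[:, cols].sum(axis=1) > 0).sum())
        c_with = int((h_ctrl[:, cols].sum(axis=1) > 0).sum())
        _, p = fisher_exact_2x2(
            t_with, len(h_test) - t_with, c_with, len(h_ctrl) - c_with
        )
        ps.append(p)
        groups.append(cols)
    qs = bh_fdr(ps)
    df["fisher_p"] = np.nan
    df["q"] = np.nan
    for cols, p, q in zip(groups, ps, qs):
        df.loc[df.index[cols], "fisher_p"] = p
        df.loc[df.index[cols], "q"] = q
    df["significant"] = df["q"] <= fdr
    return df


# ---------------------------------------------------------------------------
# base composition and AT content

def base_composition_and_at(
    sites: list[MaxTssSite],
    genome: GenomePair,
    window: int = 50,
    at_bin: int = 5,
) -> dict:
    """High-vs-low-allele base composition around the maxTSS.

    Returns per-offset base-frequency differences (high - low), per-5-bp
    AT-fraction differences with initiator offsets (-1, 0) masked, and the
    per-site AT->GC SNP offsets used by the enrichment test.  Sites with
    equal allelic depth (no high allele) are excluded.
    """
    offsets = np.arange(-window, window + 1)
    masked = {-1, 0}
    freq = {a: np.zeros((len(offsets), 4)) for a in ("high", "low")}
    base_idx = {b: i for i, b in enumerate("ACGT")}
    at_gc_offsets: list[list[int]] = []
    n_used = 0
    for s in sites:
        high = s.high_allele
        if high is None:
            continue
        low = "A2" if high == "A1" else "A1"
        seqs = {}
        for role, allele in (("high", high), ("low", low)):
            local = s.pos if allele == "A1" else genome.a1_to_a2(s.pos)
            seqs[role] = oriented_window(genome.seq(allele), local, -window, window, s.strand)
        n_used += 1
        site_atgc = []
        for k, off in enumerate(offsets):
            bh, bl = seqs["high"][k], seqs["low"][k]
            freq["high"][k, base_idx[bh]] += 1
            freq["low"][k, base_idx[bl]] += 1
            if off not in masked and bh != bl and bh in "AT" and bl in "GC":
                site_atgc.append(int(off))
        at_gc_offsets.append(site_atgc)
    if n_used == 0:
        raise ValueError("no sites with a defined high allele")
    for a in freq:
        freq[a] /= n_used

    at_rows = []
    for start in range(-window, window, at_bin):
        sel = [
            k
            for k, off in enumerate(offsets)
            if start <= off < start + at_bin and off not in masked
        ]
        at_high = freq["high"][sel][:, [0, 3]].sum() / len(sel)
        at_low = freq["low"][sel][:, [0, 3]].sum() / len(sel)
        n_sites_atgc = sum(
            1 for offs in at_gc_offsets if any(start <= o < start + at_bin for o in offs)
        )
        at_rows.append(
            {
                "bin_start": start,
                "bin_end": start + at_bin,
                "at_high": at_high,
                "at_low": at_low,
                "at_diff": at_high - at_low,
                "n_sites_at_to_gc": n_sites_atgc,
            }
        )
    return {
        "offsets": offsets,
        "freq_high": freq["high"],
        "freq_low": freq["low"],
        "freq_diff": freq["high"] - freq["low"],
        "at_windows": pd.DataFrame(at_rows),
        "n_sites": n_used,
        "at_gc_offsets": at_gc_offsets,
    }


def at_gc_enrichment(
    test: dict, control: dict, at_bin: int = 5, fdr: float = 0.05
) -> pd.DataFrame:
    """Per-window Fisher test of AT(high)->GC(low) SNP counts, test vs
    control ``base_composition_and_at`` outputs, BH-adjusted."""
    t, c = test["at_windows"], control["at_windows"]
    ps = []
    for row_t, row_c in zip(t.itertuples(), c.itertuples()):
        _, p = fisher_exact_2x2(
            row_t.n_sites_at_to_gc,
            test["n_sites"] - row_t.n_sites_at_to_gc,
            row_c.n_sites_at_to_gc,
            control["n_sites"] - row_c.n_sites_at_to_gc,
        )
        ps.append(p)
    out = t[["bin_start", "bin_end"]].copy()
    out["p"] = ps
    out["q"] = bh_fdr(ps)
    out["significant"] = out["q"] <= fdr
    return out


# ---------------------------------------------------------------------------
# TATA scoring

@dataclass
class Pwm:
    """Position weight matrix scored as log2 odds against a first-order
    Markov background."""

    motif_id: str
    probs: np.ndarray            # (L, 4) column probabilities over ACGT
    threshold: float = 3.0

    def __post_init__(self):
        if not np.allclose(self.probs.sum(axis=1), 1.0):
            raise ValueError("PWM columns must sum to 1")

    def score(self, seq: str, background: "MarkovBackground") -> float:
        """Max log2-odds over all placements in ``seq``; -inf if too short."""
        L = self.probs.shape[0]
        best = -math.inf
        idx = {b: i for i, b in enumerate("ACGT")}
        for start in range(0, len(seq) - L + 1):
            s = 0.0
            for j in range(L):
                b = seq[start + j]
                prev = seq[start + j - 1] if start + j > 0 else None
                s += math.log2(self.probs[j, idx[b]] / background.prob(b, prev))
            best = max(best, s)
        return best


class MarkovBackground:
    """First-order Markov base model estimated from a genome sequence."""

    def __init__(self, seq: str):
        idx = {b: i for i, b in enumerate("ACGT")}
        counts = np.ones((4, 4))
        marg = np.ones(4)
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        codes = np.full(arr.size, -1, dtype=np.int8)
        for b, i in idx.items():
            codes[arr == ord(b)] = i
        marg += np.bincount(codes[codes >= 0], minlength=4)
        valid = (codes[:-1] >= 0) & (codes[1:] >= 0)
        np.add.at(counts, (codes[:-1][valid], codes[1:][valid]), 1)
        self.marginal = marg / marg.sum()
        self.conditional = counts / counts.sum(axis=1, keepdims=True)
        self._idx = idx

    def prob(self, base: str, prev: str | None) -> float:
        if prev is None:
            return float(self.marginal[self._idx[base]])
        return float(self.conditional[self._idx[prev], self._idx[base]])


def bundled_pwms() -> dict[str, Pwm]:
    """Two TATA-box PWMs: a degenerate AT-rich model and a strict
    TATAAA-like consensus (synthetic stand-ins, user-replaceable)."""

    def cols(spec: list[dict[str, float]]) -> np.ndarray:
        out = np.zeros((len(spec), 4))
        for j, d in enumerate(spec):
            for b, p in d.items():
                out[j, "ACGT".index(b)] = p
        return out / out.sum(axis=1, keepdims=True)

    soft = cols(
        [
            {"T": 0.5, "A": 0.3, "C": 0.1, "G": 0.1},
            {"A": 0.5, "T": 0.3, "C": 0.1, "G": 0.1},
            {"T": 0.5, "A": 0.3, "C": 0.1, "G": 0.1},
            {"A": 0.6, "T": 0.2, "C": 0.1, "G": 0.1},
            {"A": 0.4, "T": 0.4, "C": 0.1, "G": 0.1},
            {"A": 0.6, "T": 0.2, "C": 0.1, "G": 0.1},
        ]
    )
    strict = cols(
        [
            {"T": 0.85, "A": 0.05, "C": 0.05, "G": 0.05},
            {"A": 0.85, "T": 0.05, "C": 0.05, "G": 0.05},
            {"T": 0.85, "A": 0.05, "C": 0.05, "G": 0.05},
            {"A": 0.85, "T": 0.05, "C": 0.05, "G": 0.05},
            {"A": 0.85, "T": 0.05, "C": 0.05, "G": 0.05},
            {"A": 0.85, "T": 0.05, "C": 0.05, "G": 0.05},
        ]
    )
    return {"tata_soft": Pwm("tata_soft", soft), "tata_strict": Pwm("tata_strict", strict)}


def tata_association(
    sites: list[MaxTssSite],
    genome: GenomePair,
    pwm: Pwm,
    window: tuple[int, int] = (-35, -20),
    background: MarkovBackground | None = None,
) -> tuple[pd.DataFrame, float, float]:
    """Allelic TATA-score difference vs allelic usage difference.

    Scores the -35..-20 window on each allele's own sequence; keeps sites
    where at least one allele scores above the PWM threshold; returns the
    per-site table plus Pearson (r, p) of delta-score against delta-usage
    (log2 allelic read ratio, 0.5 pseudocount).  (nan, nan) when degenerate.
    """
    bg = background or MarkovBackground(genome.seq1)
    lo, hi = window
    rows = []
    for s in sites:
        scores = {}
        try:
            for allele in ("A1", "A2"):
                local = s.pos if allele == "A1" else genome.a1_to_a2(s.pos)
                seq = oriented_window(genome.seq(allele), local, lo, hi, s.strand)
                scores[allele] = pwm.score(seq, bg)
        except IndexError:
            continue
        if max(scores.values()) <= pwm.threshold:
            continue
        d_usage = math.log2((s.count_a1 + 0.5) / (s.count_a2 + 0.5))
        rows.append(
            {
                "site_id": s.site_id,
                "score_a1": scores["A1"],
                "score_a2": scores["A2"],
                "d_score": scores["A1"] - scores["A2"],
                "d_usage": d_usage,
            }
        )
    table = pd.DataFrame(rows, columns=["site_id", "score_a1", "score_a2", "d_score", "d_usage"])
    if len(table) < 3 or table["d_score"].nunique() < 2 or table["d_usage"].nunique() < 2:
        return table, math.nan, math.nan
    r, p = sps.pearsonr(table["d_score"], table["d_usage"])
    return table, float(r), float(p)


# ---------------------------------------------------------------------------
# shooting gallery

def shooting_ratio(low_count: int, high_count: int, pseudocount: float = 0.5) -> float:
    """Redistribution ratio at a candidate initiator: low-allele signal over
    high-allele signal."""
    return (low_count + pseudocount) / (high_count + pseudocount)


def shooting_gallery(
    sites: list[MaxTssSite],
    genome: GenomePair,
    counts_by_pos: dict[tuple[int, str], tuple[int, int]],
    window: int = 20,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-candidate-initiator redistribution ratios around each maxTSS.

    ``counts_by_pos`` maps (allele-1 position, strand) to (a1, a2) 5'-end
    counts.  A site is a *test* site when its high allele initiates at CA
    and the low allele does not; a *control* site when the high allele's
    initiator is not CA.  Candidate initiators are YR dinucleotides present
    on both alleles at the same allele-1-projected offset; the central
    maxTSS itself is excluded.
    """
    rows = []
    for s in sites:
        high = s.high_allele
        if high is None:
            continue
        low = "A2" if high == "A1" else "A1"
        d_high = initiator_dinuc(genome, s.pos, s.strand, high)
        d_low = initiator_dinuc(genome, s.pos, s.strand, low)
        if d_high == "CA" and d_low != "CA":
            group = "test"
        elif d_high != "CA":
            group = "control"
        else:
            continue
        for off in range(-window, window + 1):
            if off == 0:
                continue
            pos = downstream(s.pos, off, s.strand)
            d1 = initiator_dinuc(genome, pos, s.strand, "A1")
            d2 = initiator_dinuc(genome, pos, s.strand, "A2")
            if d1 not in YR or d1 != d2:
                continue
            a1, a2 = counts_by_pos.get((pos, s.strand), (0, 0))
            low_c, high_c = (a2, a1) if high == "A1" else (a1, a2)
            rows.append(
                {
                    "site_id": s.site_id,
                    "group": group,
                    "offset": off,
                    "dinuc": d1,
                    "ratio": shooting_ratio(low_c, high_c, pseudocount),
                }
            )
    return pd.DataFrame(rows, columns=["site_id", "group", "offset", "dinuc", "ratio"])


def shooting_gallery_compare(
    table: pd.DataFrame, bin_width: int = 10, fdr: float = 0.05
) -> pd.DataFrame:
    """Test-vs-control rank-sum comparison of redistribution ratios per
    distance bin (|offset| binned), BH-adjusted."""
    if table.empty:
        return pd.DataFrame(columns=["bin_start", "bin_end", "median_test", "median_control", "p", "q"])
    table = table.assign(dist=table["offset"].abs())
    rows = []
    for start in range(1, int(table["dist"].max()) + 1, bin_width):
        sel = table[(table["dist"] >= start) & (table["dist"] < start + bin_width)]
        t = sel.loc[sel["group"] == "test", "ratio"].to_numpy()
        c = sel.loc[sel["group"] == "control", "ratio"].to_numpy()
        rows.append(
            {
                "bin_start": start,
                "bin_end": start + bin_width,
                "median_test": float(np.median(t)) if t.size else math.nan,
                "median_control": float(np.median(c)) if c.size else math.nan,
                "p": wilcoxon_rank_sum(t, c),
            }
        )
    out = pd.DataFrame(rows)
    valid = ~out["p"].isna()
    out["q"] = np.nan
    if valid.any():
        out.loc[valid, "q"] = bh_fdr(out.loc[valid, "p"].to_numpy())
    out["significant"] = out["q"] <= fdr
    return out
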