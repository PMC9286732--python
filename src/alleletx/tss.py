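"""TSS, TSC, TSR and pause calling from allele-tagged read ends.

The 5' end of each nascent RNA marks where Pol II initiated; the 3' end
marks the active site.  A TSS is any base inside a candidate regulatory
region carrying at least ``min_reads`` 5' ends (pooled across alleles);
TSSs within 60 bp chain into transcription start clusters (TSCs), whose
highest-count member(s) are the maxTSS set; all TSCs inside one candidate
region form a transcription start region (TSR).  The maxPause is the modal
3'-end base of an allele within a region.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ALLELE_CLASSES = ("A1", "A2", "untagged")


@dataclass(frozen=True)
class CandidateRegion:
    contig: str
    start: int
    end: int
    region_id: str = ""
    source: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty region {self.contig}:{self.start}-{self.end}")


@dataclass
class SiteCounts:
    """Strand-aware per-base read-end counts per allele class."""

    df: pd.DataFrame  # columns: contig, strand, pos, A1, A2, untagged, all
    end_type: str     # "five_prime" | "three_prime"

    def in_region(self, contig: str, start: int, end: int, strand: str | None = None) -> pd.DataFrame:
        m = (self.df["contig"] == contig) & (self.df["pos"] >= start) & (self.df["pos"] < end)
        if strand is not None:
            m &= self.df["strand"] == strand
        return self.df[m]


def make_base_counts(
    reads: pd.DataFrame,
    end_type: str = "five_prime",
    organ: str | None = None,
    cross: str | None = None,
    replicate: int | None = None,
) -> SiteCounts:
    """Per-base counts of read 5' or 3' ends, split by allele class.

    Untagged reads contribute to ``all`` and ``untagged`` only.
    """
    if end_type not in ("five_prime", "three_prime"):
        raise ValueError(end_type)
    df = reads
    for col, val in (("organ", organ), ("cross", cross), ("replicate", replicate)):
        if val is not None:
            df = df[df[col] == val]
    grouped = (
        df.groupby(["contig", "strand", end_type, "allele"], observed=True)
        .size()
        .unstack("allele", fill_value=0)
        .reindex(columns=list(ALLELE_CLASSES), fill_value=0)
        .reset_index()
        .rename(columns={end_type: "pos"})
    )
    grouped["all"] = grouped[list(ALLELE_CLASSES)].sum(axis=1)
    grouped = grouped.sort_values(["contig", "strand", "pos"]).reset_index(drop=True)
    return SiteCounts(grouped, end_type)


def call_tss(counts: SiteCounts, regions: list[CandidateRegion], min_reads: int = 5) -> pd.DataFrame:
    """TSSs = bases with >= min_reads pooled 5' ends inside a candidate region."""
    if counts.end_type != "five_prime":
        raise ValueError("TSS calling requires 5'-end counts")
    if not regions:
        log.warning("no candidate regions supplied; no TSSs called")
        return _empty_tss()
    out = []
    for i, reg in enumerate(regions):
        rid = reg.region_id or f"region_{i:05d}"
        sub = counts.in_region(reg.contig, reg.start, reg.end)
        sub = sub[sub["all"] >= min_reads]
        if len(sub):
            sub = sub.copy()
            sub["region_id"] = rid
            out.append(sub)
    if not out:
        return _empty_tss()
    return pd.concat(out, ignore_index=True)


def _empty_tss() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["contig", "strand", "pos", "A1", "A2", "untagged", "all", "region_id"]
    )


@dataclass
class Tsc:
    contig: str
    strand: str
    region_id: str
    members: pd.DataFrame = field(repr=False)  # per-TSS rows, sorted by pos
    tsc_id: str = ""

    @property
    def start(self) -> int:
        return int(self.members["pos"].min())

    @property
    def end(self) -> int:
        return int(self.members["pos"].max()) + 1

    @property
    def max_tss(self) -> list[int]:
        """All members tied at the maximal pooled count."""
        top = self.members["all"].max()
        return [int(p) for p in self.members.loc[self.members["all"] == top, "pos"]]

    @property
    def max_tss_primary(self) -> int:
        """Deterministic representative: the 5'-most tied maxTSS."""
        ties = self.max_tss
        return min(ties) if self.strand == "+" else max(ties)

    def allele_counts(self, allele: str) -> np.ndarray:
        return self.members[allele].to_numpy()


def cluster_tsc(tss: pd.DataFrame, merge_gap: int = 60) -> list[Tsc]:
    """Single-linkage chaining of TSSs within ``merge_gap`` bp, per
    contig/strand/region."""
    clusters: list[Tsc] = []
    if tss.empty:
        return clusters
    for (contig, strand, rid), grp in tss.groupby(["contig", "strand", "region_id"], observed=True):
        grp = grp.sort_values("pos").reset_index(drop=True)
        breaks = np.flatnonzero(np.diff(grp["pos"].to_numpy()) > merge_gap)
        starts = np.r_[0, breaks + 1]
        ends = np.r_[breaks + 1, len(grp)]
        for s, e in zip(starts, ends):
            clusters.append(Tsc(contig, strand, rid, grp.iloc[s:e].reset_index(drop=True)))
    for i, c in enumerate(clusters):
        c.tsc_id = f"tsc_{i:05d}"
    return clusters


def assign_tsr(tscs: list[Tsc]) -> dict[tuple[str, str], list[Tsc]]:
    """Group TSCs into TSRs: one per (candidate region, strand)."""
    tsrs: dict[tuple[str, str], list[Tsc]] = {}
    for tsc in tscs:
        tsrs.setdefault((tsc.region_id, tsc.strand), []).append(tsc)
    return tsrs


def call_max_pause(
    counts: SiteCounts,
    region: CandidateRegion,
    allele: str,
    strand: str,
    min_reads: int = 5,
) -> int | None:
    """Modal allelic 3'-end base in a region; 5'-most base on ties.

    Returns None when the allele has fewer than ``min_reads`` reads there.
    """
    if counts.end_type != "three_prime":
        raise ValueError("pause calling requires 3'-end counts")
    sub = counts.in_region(region.contig, region.start, region.end, strand)
    if sub[allele].sum() < min_reads:
        return None
    top = sub[allele].max()
    ties = sub.loc[sub[allele] == top, "pos"]
    return int(ties.min() if strand == "+" else ties.max())


@dataclass
class PausePair:
    region_id: str
    strand: str
    max_tss: dict[str, int]
    max_pause: dict[str, int | None]
    distance: dict[str, float]
    valid: bool
    reason: str = ""


def pair_tss_pause(
    region_id: str,
    strand: str,
    max_tss: dict[str, int],
    max_pause: dict[str, int | None],
    window: tuple[int, int] = (10, 50),
) -> PausePair:
    """Pair allelic maxTSS with allelic maxPause; valid when the strand-aware
    TSS->pause distance is inside ``window`` on both alleles."""
    lo, hi = window
    dist: dict[str, float] = {}
    reason = ""
    for allele in ("A1", "A2"):
        mp = max_pause.get(allele)
        if mp is None:
            dist[allele] = math.nan
            reason = reason or f"no maxPause on {allele}"
            continue
        d = mp - max_tss[allele] if strand == "+" else max_tss[allele] - mp
        dist[allele] = float(d)
        if not lo <= d <= hi:
            reason = reason or f"distance {d} outside [{lo},{hi}] on {allele}"
    valid = reason == ""
    return PausePair(region_id, strand, dict(max_tss), dict(max_pause), dist, valid, reason)
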