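"""Gene-body quantification, normalization and allelic ratio matrices."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .termination import TranscriptionUnit

log = logging.getLogger(__name__)


def gene_body_counts(
    reads: pd.DataFrame,
    units: list[TranscriptionUnit],
    skip: int = 500,
    min_length: int = 10_000,
    min_reads: int = 5,
    sample_cols: tuple[str, ...] = ("organ", "cross", "replicate"),
) -> pd.DataFrame:
    """Strand-specific read counts in [start+skip, end) of each gene body.

    The first ``skip`` bp downstream of the annotated start (strand-aware)
    are excluded so promoter-proximal pausing does not dominate.  Genes
    shorter than ``min_length`` or lacking ``min_reads`` in any sample are
    kept but flagged (``pass_filter``); units shorter than ``skip`` are
    excluded with a warning.  Returns a tidy frame: gene x sample x counts
    (total and per allele) plus rpkm on the total.
    """
    frames = []
    total_by_sample = reads.groupby(list(sample_cols), observed=True).size()
    for u in units:
        ulen = u.end - u.start
        if ulen <= skip:
            log.warning("unit %s shorter than gene-body skip; excluded", u.gene_id)
            continue
        if u.strand == "+":
            lo, hi = u.start + skip, u.end
        else:
            lo, hi = u.start, u.end - skip
        m = (
            (reads["contig"] == u.contig)
            & (reads["strand"] == u.strand)
            & (reads["five_prime"] >= lo)
            & (reads["five_prime"] < hi)
        )
        sub = reads[m]
        counts = sub.groupby(list(sample_cols), observed=True).size().rename("count")
        a1 = (
            sub[sub["allele"] == "A1"].groupby(list(sample_cols), observed=True).size().rename("A1")
        )
        a2 = (
            sub[sub["allele"] == "A2"].groupby(list(sample_cols), observed=True).size().rename("A2")
        )
        df = (
            pd.concat([counts, a1, a2], axis=1)
            .reindex(total_by_sample.index, fill_value=0)
            .fillna(0)
            .astype(int)
        )
        df = df.reset_index()
        df["gene"] = u.gene_id
        df["length"] = ulen - skip
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=list(sample_cols) + ["count", "A1", "A2", "gene", "length"])
    out = pd.concat(frames, ignore_index=True)
    depth = out.merge(
        total_by_sample.rename("sample_total").reset_index(), on=list(sample_cols)
    )["sample_total"]
    out["rpkm"] = out["count"] / (out["length"] / 1e3) / (depth / 1e6)
    min_per_gene = out.groupby("gene")["count"].transform("min")
    out["pass_filter"] = (out["length"] + skip >= min_length) & (min_per_gene >= min_reads)
    return out


def spearman_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlation of samples (columns); constant columns
    yield NaN against every partner."""
    cols = matrix.columns
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for j in range(i + 1, len(cols)):
            cj = cols[j]
            x, y = matrix[ci].to_numpy(), matrix[cj].to_numpy()
            if np.all(x == x[0]) or np.all(y == y[0]):
                rho = np.nan
            else:
                rho = sps.spearmanr(x, y).statistic
            out.loc[ci, cj] = out.loc[cj, ci] = rho
    return out


def allelic_ratio_matrix(
    counts: pd.DataFrame,
    pseudocount: float = 0.5,
    min_specific_samples: int = 3,
    specific_q: pd.DataFrame | None = None,
    fdr: float = 0.10,
) -> pd.DataFrame:
    """Genes x samples matrix of log2((A1 + pc) / (A2 + pc)).

    ``counts`` is the tidy gene_body_counts output.  When ``specific_q``
    (genes x samples BH q-values) is given, genes must be allele-specific
    (q <= fdr) in at least ``min_specific_samples`` samples to be retained.
    """
    counts = counts.copy()
    counts["sample"] = counts[["organ", "cross", "replicate"]].astype(str).agg("_".join, axis=1)
    mat = counts.pivot_table(index="gene", columns="sample", values=["A1", "A2"], aggfunc="sum")
    ratio = np.log2((mat["A1"] + pseudocount) / (mat["A2"] + pseudocount))
    if specific_q is not None:
        keep = (specific_q <= fdr).sum(axis=1) >= min_specific_samples
        ratio = ratio.loc[ratio.index.intersection(keep[keep].index)]
    return ratio
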