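"""Readers and writers for the plain-text formats the pipeline touches.

All interval semantics are 0-based half-open internally; GTF-like 1-based
inclusive coordinates are converted at the boundary.  Read-end tables are
TSV with a header; signal tracks are bedGraph, one file per strand and
allele class, with adjacent equal-value runs merged.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .sim.genome import GenomePair
from .termination import TranscriptionUnit
from .tss import ALLELE_CLASSES, CandidateRegion, SiteCounts

log = logging.getLogger(__name__)

READ_TSV_COLUMNS = [
    "contig", "five_prime", "three_prime", "strand", "allele",
    "organ", "cross", "replicate",
]
_STRANDS = {"+", "-"}
_ALLELES = set(ALLELE_CLASSES)


def read_read_ends(path: str | Path) -> pd.DataFrame:
    """Read and validate an allelic read-end TSV; malformed lines raise with
    their line number."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in READ_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.empty:
        log.warning("%s: empty read table", path)
        return df
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.strand not in _STRANDS:
            raise ValueError(f"{path}:{i}: unknown strand {row.strand!r}")
        if row.allele not in _ALLELES:
            raise ValueError(f"{path}:{i}: unknown allele {row.allele!r}")
        if row.strand == "+" and row.five_prime > row.three_prime:
            raise ValueError(f"{path}:{i}: 5' end downstream of 3' end on + strand")
        if row.strand == "-" and row.three_prime > row.five_prime:
            raise ValueError(f"{path}:{i}: 3' end downstream of 5' end on - strand")
    return df


def write_read_ends(reads: pd.DataFrame, path: str | Path) -> None:
    reads[READ_TSV_COLUMNS].to_csv(path, sep="\t", index=False)


def write_read_bed6(reads: pd.DataFrame, path: str | Path) -> None:
    """BED6 export: one interval per read spanning 5'..3' end."""
    lo = reads[["five_prime", "three_prime"]].min(axis=1)
    hi = reads[["five_prime", "three_prime"]].max(axis=1) + 1
    bed = pd.DataFrame(
        {
            "contig": reads["contig"],
            "start": lo,
            "end": hi,
            "name": reads["allele"],
            "score": 0,
            "strand": reads["strand"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_intervals(path: str | Path, fmt: str = "bed", kind: str = "region"):
    """Read BED or GTF-like intervals as CandidateRegion or TranscriptionUnit.

    BED is 0-based half-open as on disk; GTF-like input (1-based inclusive)
    is converted.  ``kind`` selects the returned type ("region" | "unit").
    """
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if fmt == "bed":
                contig, start, end = f[0], int(f[1]), int(f[2])
                name = f[3] if len(f) > 3 else f"{kind}_{i:05d}"
                strand = f[5] if len(f) > 5 else "+"
            elif fmt == "gtf_like":
                contig, start, end = f[0], int(f[3]) - 1, int(f[4])
                name = f[8] if len(f) > 8 else f"{kind}_{i:05d}"
                strand = f[6]
            else:
                raise ValueError(f"unknown format {fmt!r}")
            if start < 0:
                raise ValueError(f"{path}:{i}: negative start")
            if start >= end:
                raise ValueError(f"{path}:{i}: start >= end")
            if kind == "unit":
                out.append(TranscriptionUnit(contig, start, end, strand, name))
            else:
                out.append(CandidateRegion(contig, start, end, name))
    return out


def write_intervals_bed(items, path: str | Path) -> None:
    with open(path, "w") as fh:
        for it in items:
            name = getattr(it, "gene_id", getattr(it, "region_id", "."))
            strand = getattr(it, "strand", ".")
            fh.write(f"{it.contig}\t{it.start}\t{it.end}\t{name}\t0\t{strand}\n")


def write_signal_track(
    counts: SiteCounts, prefix: str | Path, alleles: tuple[str, ...] = ("all",)
) -> list[Path]:
    """One bedGraph per strand per allele class, sorted, runs merged."""
    paths = []
    prefix = Path(prefix)
    for allele in alleles:
        for strand, tag in (("+", "plus"), ("-", "minus")):
            sub = counts.df[counts.df["strand"] == strand]
            sub = sub[sub[allele] > 0].sort_values(["contig", "pos"])
            path = Path(f"{prefix}_{allele}_{tag}.bedGraph")
            with open(path, "w") as fh:
                run = None  # [contig, start, end, value]
                for row in sub.itertuples(index=False):
                    v = getattr(row, allele)
                    if run and run[0] == row.contig and run[2] == row.pos and run[3] == v:
                        run[2] += 1
                        continue
                    if run:
                        fh.write(f"{run[0]}\t{run[1]}\t{run[2]}\t{run[3]}\n")
                    run = [row.contig, row.pos, row.pos + 1, v]
                if run:
                    fh.write(f"{run[0]}\t{run[1]}\t{run[2]}\t{run[3]}\n")
            paths.append(path)
    return paths


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=["contig", "start", "end", "value"])


def write_fasta(genome: GenomePair, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in ((f"{genome.contig}_A1", genome.seq1), (f"{genome.contig}_A2", genome.seq2)):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_vcf(genome: GenomePair, path: str | Path) -> None:
    """Minimal VCF (CHROM POS ID REF ALT) of the allele-1 -> allele-2 variants."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\n")
        for i, v in enumerate(genome.variants):
            fh.write(f"{genome.contig}\t{v.position + 1}\tv{i}\t{v.ref}\t{v.alt}\n")


def read_vcf_variants(path: str | Path):
    from .sim.genome import Variant

    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            contig, pos, _id, ref, alt = line.rstrip("\n").split("\t")[:5]
            out.append(Variant(int(pos) - 1, ref, alt))
    return out
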