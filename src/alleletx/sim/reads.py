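"""Simulate allele-tagged nascent-RNA read ends and exon-level mRNA counts.

Each simulated read is one nascent RNA: its 5' end marks the TSS that fired,
its 3' end marks the Pol II active site — either the allele's pause position
plus a small truncated-geometric jitter, or (for a configurable fraction) a
uniform position along the allele's own transcription unit, which is what
carries the allelic-termination signal.  All randomness comes from child
streams of the run seed; nothing global.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd

from .config import CROSSES, SimConfig
from .generate import LocusTruth, TruthSet
from .plan import downstream

READ_COLUMNS = [
    "contig", "five_prime", "three_prime", "strand", "allele",
    "organ", "cross", "replicate", "locus", "source_allele",
    "local_five", "local_three",
]


def _jitter_kernel(p: float, max_abs: int) -> tuple[np.ndarray, np.ndarray]:
    offs = np.arange(-max_abs, max_abs + 1)
    w = (1.0 - p) ** np.abs(offs)
    return offs, w / w.sum()


def _maternal(cross: str) -> str:
    return "A1" if cross == "A1xA2" else "A2"


def _locus_counts(rng: np.random.Generator, means: np.ndarray, overdisp: float) -> np.ndarray:
    if overdisp > 0:
        shape = 1.0 / overdisp
        return rng.poisson(rng.gamma(shape, means * overdisp))
    return rng.poisson(means)


def simulate_read_ends(truth: TruthSet, config: SimConfig | None = None) -> pd.DataFrame:
    config = config or truth.config
    rng = np.random.default_rng([config.seed, 103])
    offs, jprob = _jitter_kernel(config.pause_jitter_p, config.pause_jitter_max)
    genome = truth.genome
    chunks: list[pd.DataFrame] = []
    samples = list(product(config.organs, CROSSES, range(1, config.n_replicates + 1)))
    # reads_per_tsc is the target *tagged* depth; with no tagging at all it
    # degrades to the total depth
    if config.tagging_prob > 0:
        total_per_locus = config.reads_per_tsc / config.tagging_prob
    else:
        total_per_locus = config.reads_per_tsc

    for organ, cross, rep in samples:
        mom = _maternal(cross)
        for locus in truth.loci:
            mult = {a: (locus.imprint_mult if a == mom else 1.0) for a in ("A1", "A2")}
            lam = np.array([[t.rate[a] * mult[a] for a in ("A1", "A2")] for t in locus.tss])
            lam = lam / lam.sum() * total_per_locus
            counts = _locus_counts(rng, lam, config.overdispersion)
            sign = 1 if locus.strand == "+" else -1
            for j, tss in enumerate(locus.tss):
                for ai, allele in enumerate(("A1", "A2")):
                    n = int(counts[j, ai])
                    if n == 0:
                        continue
                    tss_local = tss.pos_a1 if allele == "A1" else tss.pos_a2_local
                    is_body = rng.random(n) < config.body_read_fraction
                    jit = rng.choice(offs, size=n, p=jprob)
                    local3 = locus.pause_local[allele] + sign * jit
                    # the pause is anchored at the maxTSS; a member TSS just
                    # upstream of it cannot have its active site before its
                    # own 5' end
                    if locus.strand == "+":
                        local3 = np.maximum(local3, tss_local)
                    else:
                        local3 = np.minimum(local3, tss_local)
                    # promoter-proximal reads keep the capped 5' end = TSS;
                    # gene-body reads are run-on fragments whose 5' end sits
                    # an insert length upstream of the polymerase
                    local5 = np.full(n, tss_local, dtype=np.int64)
                    nb = int(is_body.sum())
                    if nb:
                        lo = locus.pause_offset_obs[allele] + 5
                        hi = locus.unit_local_len[allele]
                        body_off = rng.integers(lo, hi, size=nb)
                        insert = rng.integers(20, 61, size=nb)
                        local3[is_body] = tss_local + sign * body_off
                        local5[is_body] = tss_local + sign * np.maximum(body_off - insert, 0)
                    local3 = local3.astype(np.int64)
                    if allele == "A1":
                        three1 = local3
                        five1 = local5
                    else:
                        three1 = genome.a2_to_a1_array(local3)
                        five1 = genome.a2_to_a1_array(local5)
                    tagged = rng.random(n) < config.tagging_prob
                    chunks.append(
                        pd.DataFrame(
                            {
                                "contig": locus.contig,
                                "five_prime": five1,
                                "three_prime": three1,
                                "strand": locus.strand,
                                "allele": np.where(tagged, allele, "untagged"),
                                "organ": organ,
                                "cross": cross,
                                "replicate": rep,
                                "locus": locus.gene_id,
                                "source_allele": allele,
                                "local_five": local5,
                                "local_three": local3,
                            }
                        )
                    )
    if not chunks:
        return pd.DataFrame(columns=READ_COLUMNS)
    df = pd.concat(chunks, ignore_index=True)[READ_COLUMNS]
    return df.sort_values(["contig", "five_prime", "three_prime"], kind="stable").reset_index(drop=True)


def simulate_mrna_counts(truth: TruthSet, config: SimConfig | None = None) -> pd.DataFrame:
    """Exon-level allele-specific mRNA counts per organ x cross.

    Counts are Poisson with mean = (allelic transcription rate) x (allelic
    stability multiplier) x (exon kb) x depth; a novel 3' exon is expressed
    only from the long allele of structure-change loci.
    """
    config = config or truth.config
    rng = np.random.default_rng([config.seed, 104])
    rows = []
    for organ, cross in product(config.organs, CROSSES):
        mom = _maternal(cross)
        for locus in truth.loci:
            rate = {
                a: sum(t.rate[a] for t in locus.tss)
                * (locus.imprint_mult if a == mom else 1.0)
                for a in ("A1", "A2")
            }
            stab = dict(zip(("A1", "A2"), locus.plan.stability))
            for start, end, kind in locus.exons:
                kb = (end - start) / 1000.0
                mean = {
                    a: rate[a] * stab[a] * kb * config.mrna_depth * 100.0
                    for a in ("A1", "A2")
                }
                if kind == "novel":
                    mean[_short_allele(locus)] = 0.0
                rows.append(
                    {
                        "gene": locus.gene_id,
                        "organ": organ,
                        "cross": cross,
                        "contig": locus.contig,
                        "exon_start": start,
                        "exon_end": end,
                        "exon_kind": kind,
                        "strand": locus.strand,
                        "A1": int(rng.poisson(mean["A1"])),
                        "A2": int(rng.poisson(mean["A2"])),
                    }
                )
    return pd.DataFrame(rows)


def _short_allele(locus: LocusTruth) -> str:
    return "A2" if locus.plan.long_allele == "A1" else "A1"
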