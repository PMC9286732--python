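"""The deterministic per-locus blueprint shared by genome construction and
truth planting.

The generator works in two phases that must agree exactly: first the diploid
sequences are built with promoter cassettes (initiator dinucleotides, a
G-rich pause motif, forced allelic SNPs/indels) embedded at planned
positions; then the truth set is derived by re-reading those sequences.
Both phases consume the same :class:`LocusPlan` list, produced from a
dedicated child stream of the run seed, so neither phase can drift from the
other no matter how much randomness it consumes itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import EFFECT_CLASSES, SimConfig

INITIATORS = ("CA", "TA", "TG", "CG")


@dataclass
class LocusPlan:
    index: int
    anchor: int                      # allele-1 coordinate of the maxTSS base
    strand: str
    effect_class: str
    tss_offsets: list[int]           # strand-aware downstream offsets, 0 = maxTSS
    tss_dinucs: list[str]            # allele-1 initiator at each member TSS
    tss_base_rates: list[float]
    maxtss_dinuc_a2: str             # allele-2 initiator at the maxTSS
    pause_offset: int                # planned offset of the embedded pause motif
    pause_snp_alt: str | None        # allele-2 base replacing the active-site C
    pause_indel: tuple[int, int] | None  # (downstream offset, deleted length) on allele 2
    unit_length: int                 # long-allele unit length
    short_unit_length: int           # == unit_length unless termination locus
    long_allele: str                 # allele with the longer unit
    structure_change: bool
    shape_boost: list[float] = field(default_factory=list)     # allele-1 per-TSS fold
    shape_boost_a2: list[float] = field(default_factory=list)  # allele-2 per-TSS fold
    stability: tuple[float, float] = (1.0, 1.0)             # per-allele multiplier

    @property
    def gene_id(self) -> str:
        return f"locus_{self.index:04d}"


def downstream(pos: int, d: int, strand: str) -> int:
    """Strand-aware coordinate arithmetic: +d is toward the 3' end."""
    return pos + d if strand == "+" else pos - d


def make_locus_plans(config: SimConfig) -> list[LocusPlan]:
    config.validate()
    rng = np.random.default_rng([config.seed, 101])
    classes = list(config.effect_proportions)
    probs = np.array([config.effect_proportions[c] for c in classes])
    # deterministic, proportional class assignment (shuffled), so small
    # simulations carry every planted class at its configured share
    counts = np.floor(probs * config.n_loci).astype(int)
    while counts.sum() < config.n_loci:
        counts[int(np.argmax(probs * config.n_loci - counts))] += 1
    assigned = np.repeat(classes, counts)
    rng.shuffle(assigned)

    plans: list[LocusPlan] = []
    for i in range(config.n_loci):
        slot_start = config.slot_margin + i * config.slot_width
        anchor = slot_start + config.slot_width // 2
        strand = "+" if rng.random() < 0.5 else "-"
        cls = str(assigned[i])

        n_tss = 4 if cls.startswith("shape") else int(rng.integers(1, 4))
        extra = rng.choice(np.arange(6, 31), size=n_tss - 1, replace=False)
        signs = rng.choice([-1, 1], size=n_tss - 1)
        # index 0 is always the maxTSS; member lists stay index-aligned
        offsets = [0] + [int(d * s) for d, s in zip(extra, signs)]
        dinucs = ["CA"] + [INITIATORS[int(k)] for k in rng.integers(1, 4, size=n_tss - 1)]
        base_rates = [1.0] + list(np.round(rng.uniform(0.3, 0.7, size=n_tss - 1), 3))

        dinuc_a2 = dinucs[0]
        if cls == "none" and rng.random() < config.initiator_snp_prob:
            # any ordered pair of distinct YR initiators, so every pairwise
            # category (CA>TA ... TA>TG ...) is populated
            i, j = rng.choice(4, size=2, replace=False)
            dinucs[0] = INITIATORS[int(i)]
            dinuc_a2 = INITIATORS[int(j)]

        lo, hi = config.pause_offset_range
        pause_offset = int(rng.integers(lo, hi + 1))
        pause_snp_alt = None
        if rng.random() < config.pause_snp_prob:
            pause_snp_alt = "ATG"[int(rng.integers(0, 3))]
        pause_indel = None
        if rng.random() < config.pause_indel_prob:
            ilo, ihi = config.pause_indel_lengths
            length = int(rng.integers(ilo, ihi + 1))
            # the indel must fit between the TSS and the pause motif
            length = min(length, pause_offset - 19)
            pos = int(rng.integers(5, pause_offset - 12 - length))
            pause_indel = (pos, length)

        unit_length = int(rng.integers(*config.unit_length_range))
        short_len = unit_length
        long_allele = "A1"
        structure_change = False
        if cls == "termination":
            frac = rng.uniform(*config.termination_frac_range)
            short_len = int(round(unit_length * (1.0 - frac)))
            long_allele = "A1" if rng.random() < 0.5 else "A2"
            structure_change = rng.random() < config.structure_change_prob

        boost = [1.0] * n_tss
        boost2 = [1.0] * n_tss
        if cls == "shape_single":
            boost[int(rng.integers(1, n_tss))] = config.shape_single_fold
        elif cls == "shape_multi":
            # three secondary TSSs shifted, split across the alleles (one on
            # one allele, two on the other): a same-direction uniform boost
            # collapses to a single-TSS change after renormalization, and
            # this split keeps a substantial redistribution visible after
            # any single member is masked
            chosen = rng.permutation(np.arange(1, n_tss))[:3]
            first, rest = ([boost, boost2] if rng.random() < 0.5 else [boost2, boost])
            first[int(chosen[0])] = config.shape_multi_fold
            for j in chosen[1:]:
                rest[int(j)] = config.shape_multi_fold

        stab = float(np.exp(rng.normal(0.0, 0.1)))
        stability = (stab, stab)
        if structure_change:
            shifted = stab * config.stability_shift
            stability = (shifted, stab) if long_allele == "A1" else (stab, shifted)

        plans.append(
            LocusPlan(
                index=i,
                anchor=anchor,
                strand=strand,
                effect_class=cls,
                tss_offsets=offsets,
                tss_dinucs=dinucs,
                tss_base_rates=base_rates,
                maxtss_dinuc_a2=dinuc_a2,
                pause_offset=pause_offset,
                pause_snp_alt=pause_snp_alt,
                pause_indel=pause_indel,
                unit_length=unit_length,
                short_unit_length=short_len,
                long_allele=long_allele,
                structure_change=structure_change,
                shape_boost=boost,
                shape_boost_a2=boost2,
                stability=stability,
            )
        )
    assert all(c in EFFECT_CLASSES for c in assigned)
    return plans
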