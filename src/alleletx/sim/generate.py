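"""Build the diploid genome and derive the planted truth from it.

Two-phase design: :func:`generate_genome_pair` embeds promoter cassettes
(initiator dinucleotides, a G-rich pause motif ending in C, forced allelic
SNPs and indels) into otherwise random sequence and sprinkles background
heterozygosity; :func:`plant_truth` then *re-reads the finished sequences*
to compute per-TSS initiation rates and per-allele pause positions, so the
truth is a deterministic function of the DNA exactly as the generative model
claims:

    rate(TSS, allele) = base * w[initiator dinucleotide at (-1, 0)]
                        * exp(alpha * AT fraction of the +/-5 bp window,
                              positions -1/0 excluded)

    pause(allele) = argmin offset in [20, 60] maximizing
                    w_C * [base == C] + w_G * (# G in the 10 bp upstream),
                    computed on that allele's own sequence
                    ("energy" mode), or TSS + fixed offset in allele-local
                    coordinates ("pic" mode).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimConfig
from .genome import GenomePair, Variant, random_sequence
from .plan import LocusPlan, downstream, make_locus_plans

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

PAUSE_MIN, PAUSE_MAX = 20, 60


def _set_offset_base(seq: bytearray, anchor: int, off: int, base: str, strand: str) -> None:
    """Write a transcribed-strand base at a strand-aware offset from anchor."""
    pos = downstream(anchor, off, strand)
    seq[pos] = ord(base if strand == "+" else _COMP[base])


def _offset_base(seq: str, anchor: int, off: int, strand: str) -> str:
    pos = downstream(anchor, off, strand)
    b = seq[pos]
    return b if strand == "+" else _COMP[b]


def oriented_window(seq: str, anchor: int, lo: int, hi: int, strand: str) -> str:
    """Transcribed-strand sequence from offset lo to hi (inclusive) around anchor."""
    if strand == "+":
        return seq[anchor + lo : anchor + hi + 1]
    sub = seq[anchor - hi : anchor - lo + 1]
    return "".join(_COMP[b] for b in reversed(sub))


def generate_genome_pair(config: SimConfig) -> GenomePair:
    config.validate()
    plans = make_locus_plans(config)
    rng = np.random.default_rng([config.seed, 102])
    L = config.contig_length
    seq = bytearray(random_sequence(rng, L).encode())

    forced: list[Variant] = []
    blocked = np.zeros(L, dtype=bool)
    for p in plans:
        core_lo = min(downstream(p.anchor, -45, p.strand), downstream(p.anchor, 70, p.strand))
        core_hi = max(downstream(p.anchor, -45, p.strand), downstream(p.anchor, 70, p.strand))
        blocked[max(core_lo - 6, 0) : core_hi + 7] = True

        for off, dinuc in zip(p.tss_offsets, p.tss_dinucs):
            tss = downstream(p.anchor, off, p.strand)
            _set_offset_base(seq, tss, -1, dinuc[0], p.strand)
            _set_offset_base(seq, tss, 0, dinuc[1], p.strand)
        if config.pause_mode in ("energy", "constrained"):
            for k in range(1, 11):
                _set_offset_base(seq, p.anchor, p.pause_offset - k, "G", p.strand)
            _set_offset_base(seq, p.anchor, p.pause_offset, "C", p.strand)

    seq1 = seq.decode()

    for p in plans:
        # initiator SNPs at the maxTSS (may need one or two base changes)
        if p.maxtss_dinuc_a2 != p.tss_dinucs[0]:
            for off, b1, b2 in zip((-1, 0), p.tss_dinucs[0], p.maxtss_dinuc_a2):
                if b1 != b2:
                    pos = downstream(p.anchor, off, p.strand)
                    alt = b2 if p.strand == "+" else _COMP[b2]
                    forced.append(Variant(pos, seq1[pos], alt))
        if p.pause_snp_alt is not None and config.pause_mode in ("energy", "constrained"):
            pos = downstream(p.anchor, p.pause_offset, p.strand)
            alt = p.pause_snp_alt if p.strand == "+" else _COMP[p.pause_snp_alt]
            forced.append(Variant(pos, seq1[pos], alt))
        if p.pause_indel is not None:
            off, length = p.pause_indel
            if p.strand == "+":
                dstart = p.anchor + off
            else:
                dstart = p.anchor - off - length + 1
            forced.append(Variant(dstart - 1, seq1[dstart - 1 : dstart + length], seq1[dstart - 1]))

    # background heterozygosity outside the protected promoter cores
    n_snp = rng.poisson(config.snp_density * L)
    n_ind = rng.poisson(config.indel_density * L)
    snp_pos = rng.integers(10, L - 10, size=n_snp)
    ind_pos = rng.integers(10, L - 10, size=n_ind)
    ind_len = rng.integers(1, 6, size=n_ind)
    ind_ins = rng.random(n_ind) < 0.5
    background: list[Variant] = []
    for pos in sorted(set(int(x) for x in snp_pos)):
        if blocked[pos]:
            continue
        alt = "ACGT"[int(rng.integers(0, 4))]
        if alt != seq1[pos]:
            background.append(Variant(pos, seq1[pos], alt))
    for pos, length, ins in zip(ind_pos, ind_len, ind_ins):
        pos, length = int(pos), int(length)
        if blocked[max(pos - 1, 0) : pos + length + 1].any():
            continue
        if ins:
            extra = random_sequence(rng, length)
            background.append(Variant(pos, seq1[pos], seq1[pos] + extra))
        else:
            background.append(Variant(pos, seq1[pos : pos + length + 1], seq1[pos]))

    variants = _dedupe(forced + background, len(seq1))
    return GenomePair.from_allele1(config.contig, seq1, variants)


def _dedupe(variants: list[Variant], contig_len: int) -> list[Variant]:
    """Sort and drop variants whose footprints collide (forced ones win: they
    come first in the input and are kept on ties)."""
    taken = np.zeros(contig_len, dtype=bool)
    kept = []
    for v in variants:
        lo, hi = v.position, v.position + len(v.ref)
        if taken[lo:hi].any():
            continue
        taken[lo:hi] = True
        kept.append(v)
    return sorted(kept, key=lambda v: v.position)


# ---------------------------------------------------------------------------
# truth planting


@dataclass
class TssTruth:
    offset: int
    pos_a1: int
    pos_a2_local: int
    dinuc: dict[str, str]
    rate: dict[str, float]          # strain-linked rates (imprinting excluded)


@dataclass
class LocusTruth:
    plan: LocusPlan
    contig: str
    tss: list[TssTruth]
    imprint_mult: float             # maternal-allele multiplier
    pause_local: dict[str, int]     # allele-local coordinate of the pause base
    pause_a1: dict[str, int]        # allele-1 projection of the pause
    pause_offset_obs: dict[str, int]
    unit_a1: dict[str, tuple[int, int]]   # allele-1 coords, half-open
    unit_local_len: dict[str, int]
    exons: list[tuple[int, int, str]]     # (start, end, kind) on allele 1
    at_window: tuple[int, int] | None

    @property
    def strand(self) -> str:
        return self.plan.strand

    @property
    def gene_id(self) -> str:
        return self.plan.gene_id

    @property
    def max_tss(self) -> TssTruth:
        return self.tss[0]


@dataclass
class TruthSet:
    genome: GenomePair
    config: SimConfig
    loci: list[LocusTruth]


def pause_energy_argmax(
    oriented: str, w_c: float, w_g: float,
    lo: int = PAUSE_MIN, hi: int = PAUSE_MAX,
) -> int:
    """Smallest-offset argmax of the pause energy over offsets lo..hi.

    ``oriented`` is the transcribed-strand sequence starting at the TSS
    (index 0 = TSS base) and must extend to offset ``hi``.
    """
    best, best_off = -np.inf, lo
    for off in range(lo, hi + 1):
        score = w_c * (oriented[off] == "C") + w_g * oriented[off - 10 : off].count("G")
        if score > best + 1e-12:
            best, best_off = score, off
    return best_off


def _tss_rate(oriented: str, weights: dict[str, float], w_other: float, alpha: float) -> tuple[str, float]:
    """Initiator dinucleotide and sequence-intrinsic rate factor.

    ``oriented`` is the transcribed strand from offset -6 to +5 (12 bases,
    index 6 = TSS base).
    """
    dinuc = oriented[5:7]
    w = weights.get(dinuc, w_other)
    window = oriented[1:5] + oriented[7:12]   # offsets -5..-2 and +1..+5
    at = sum(b in "AT" for b in window) / len(window)
    return dinuc, w * float(np.exp(alpha * at))


def plant_truth(genome: GenomePair, config: SimConfig) -> TruthSet:
    config.validate()
    plans = make_locus_plans(config)
    weights = config.initiator_weights()
    loci: list[LocusTruth] = []
    for p in plans:
        tss_list: list[TssTruth] = []
        for j, off in enumerate(p.tss_offsets):
            pos1 = downstream(p.anchor, off, p.strand)
            pos2 = genome.a1_to_a2(pos1)
            rates, dinucs = {}, {}
            for allele, seq, pos in (("A1", genome.seq1, pos1), ("A2", genome.seq2, pos2)):
                oriented = oriented_window(seq, pos, -6, 5, p.strand)
                dinuc, factor = _tss_rate(oriented, weights, config.w_other, config.at_coefficient)
                rate = p.tss_base_rates[j] * factor
                if allele == "A1":
                    rate *= p.shape_boost[j]
                    if p.effect_class == "abundance":
                        rate *= config.abundance_ratio
                else:
                    rate *= p.shape_boost_a2[j]
                rates[allele], dinucs[allele] = rate, dinuc
            tss_list.append(TssTruth(off, pos1, pos2, dinucs, rates))

        max1, max2 = tss_list[0].pos_a1, tss_list[0].pos_a2_local
        pause_local, pause_a1, pause_obs = {}, {}, {}
        for allele, seq, tss in (("A1", genome.seq1, max1), ("A2", genome.seq2, max2)):
            if config.pause_mode == "pic":
                off = p.pause_offset
            else:
                oriented = oriented_window(seq, tss, 0, PAUSE_MAX + 1, p.strand)
                if config.pause_mode == "constrained":
                    w = config.pause_search_halfwidth
                    lo = max(PAUSE_MIN, p.pause_offset - w)
                    hi = min(PAUSE_MAX, p.pause_offset + w)
                else:
                    lo, hi = PAUSE_MIN, PAUSE_MAX
                off = pause_energy_argmax(
                    oriented, config.pause_weight_c, config.pause_weight_g, lo, hi
                )
            loc = downstream(tss, off, p.strand)
            pause_local[allele], pause_obs[allele] = loc, off
            pause_a1[allele] = loc if allele == "A1" else genome.a2_to_a1(loc)

        unit_a1, unit_local = {}, {}
        for allele in ("A1", "A2"):
            length = p.unit_length if allele == p.long_allele else p.short_unit_length
            unit_local[allele] = length
            tss1 = max1
            end = downstream(tss1, length, p.strand)
            unit_a1[allele] = (tss1, end) if p.strand == "+" else (end + 1, tss1 + 1)

        exons = _exon_structure(p, max1)
        at_win = None
        if p.effect_class == "termination":
            s_end = downstream(max1, p.short_unit_length, p.strand)
            l_end = downstream(max1, p.unit_length, p.strand)
            at_win = (s_end, l_end) if p.strand == "+" else (l_end + 1, s_end + 1)

        loci.append(
            LocusTruth(
                plan=p,
                contig=genome.contig,
                tss=tss_list,
                imprint_mult=config.imprinted_ratio if p.effect_class == "imprinted" else 1.0,
                pause_local=pause_local,
                pause_a1=pause_a1,
                pause_offset_obs=pause_obs,
                unit_a1=unit_a1,
                unit_local_len=unit_local,
                exons=exons,
                at_window=at_win,
            )
        )
    return TruthSet(genome, config, loci)


def _exon_structure(p: LocusPlan, tss1: int) -> list[tuple[int, int, str]]:
    def span(lo_off: int, hi_off: int) -> tuple[int, int]:
        a = downstream(tss1, lo_off, p.strand)
        b = downstream(tss1, hi_off, p.strand)
        return (a, b) if p.strand == "+" else (b + 1, a + 1)

    exons = [span(0, 300) + ("shared",), span(p.short_unit_length - 400, p.short_unit_length) + ("shared",)]
    if p.structure_change:
        exons.append(span(p.unit_length - 300, p.unit_length) + ("novel",))
    return exons
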