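"""Diploid genome construction: two allele sequences, a variant table, and a
monotone coordinate map between them.

The simulated cross is an F1 hybrid between two inbred strains, so every
locus is heterozygous for exactly the variants listed in the table.  Allele 1
is the reference-like haplotype; allele 2 is derived from it by applying the
variants.  Indels are VCF-anchored (first base of ref and alt is shared), so
a variant applies at ``position`` on allele 1 as::

    allele2 = allele1[:pos] + alt + allele1[pos + len(ref):]

Coordinate projection between the two haplotypes ("liftover") is exact for
every base outside an indel footprint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Variant:
    """A single heterozygous difference between the two haplotypes.

    ``position`` is 0-based on allele 1.  SNPs have single-base ref and alt;
    indels are left-anchored with a shared first base.
    """

    position: int
    ref: str
    alt: str

    @property
    def kind(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "snp"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("variant ref and alt are identical")
        if min(len(self.ref), len(self.alt)) == 0:
            raise ValueError("indels must be anchored (non-empty ref and alt)")


@dataclass
class GenomePair:
    """The two haplotype sequences of one contig plus their alignment.

    ``segments`` holds (a1_start, a2_start, length) runs of co-linear
    coordinates; SNPs do not interrupt a run, indels do.
    """

    contig: str
    seq1: str
    seq2: str
    variants: list[Variant]
    segments: np.ndarray = field(repr=False)  # (n, 3) int64

    # -- construction ------------------------------------------------------
    @classmethod
    def from_allele1(cls, contig: str, seq1: str, variants: list[Variant]) -> "GenomePair":
        variants = sorted(variants, key=lambda v: v.position)
        _check_nonoverlap(variants, len(seq1))
        pieces: list[str] = []
        segs: list[tuple[int, int, int]] = []
        a1 = a2 = 0
        for v in variants:
            if v.kind == "snp":
                continue  # SNPs do not break co-linearity
            cut = v.position + 1  # anchored: shared first base stays aligned
            seglen = cut - a1
            segs.append((a1, a2, seglen))
            a1 = v.position + len(v.ref)
            a2 = a2 + seglen + (len(v.alt) - 1)
        segs.append((a1, a2, len(seq1) - a1))
        # build allele2 left to right
        pos = 0
        for v in variants:
            pieces.append(seq1[pos : v.position])
            pieces.append(v.alt)
            pos = v.position + len(v.ref)
        pieces.append(seq1[pos:])
        seq2 = "".join(pieces)
        for v in variants:  # SNP substitution check by construction
            if v.kind == "snp" and seq1[v.position] != v.ref:
                raise ValueError(f"variant ref mismatch at {v.position}")
        return cls(contig, seq1, seq2, variants, np.asarray(segs, dtype=np.int64))

    # -- coordinate projection --------------------------------------------
    def a2_to_a1(self, pos: int) -> int:
        """Project an allele-2 coordinate onto allele 1.

        Positions inside an insertion (no allele-1 counterpart) map to the
        last aligned base at or left of them.
        """
        return _project(self.segments[:, 1], self.segments[:, 0], self.segments[:, 2], pos)

    def a1_to_a2(self, pos: int) -> int:
        return _project(self.segments[:, 0], self.segments[:, 1], self.segments[:, 2], pos)

    def project(self, pos: int, from_allele: str) -> int:
        return self.a2_to_a1(pos) if from_allele == "A2" else self.a1_to_a2(pos)

    def a2_to_a1_array(self, pos: np.ndarray) -> np.ndarray:
        return _project_array(self.segments[:, 1], self.segments[:, 0], self.segments[:, 2], pos)

    def a1_to_a2_array(self, pos: np.ndarray) -> np.ndarray:
        return _project_array(self.segments[:, 0], self.segments[:, 1], self.segments[:, 2], pos)

    def in_indel_footprint(self, pos: int, allele: str = "A1") -> bool:
        """True when the position has no exact 1:1 counterpart on the other allele."""
        src = self.segments[:, 0] if allele == "A1" else self.segments[:, 1]
        i = int(np.searchsorted(src, pos, side="right")) - 1
        if i < 0:
            return True
        return pos >= src[i] + self.segments[i, 2]

    def seq(self, allele: str) -> str:
        return self.seq1 if allele == "A1" else self.seq2

    def window(self, allele: str, start: int, end: int) -> str:
        s = self.seq(allele)
        if start < 0 or end > len(s):
            raise IndexError("window runs off contig")
        return s[start:end]


def _project(src: np.ndarray, dst: np.ndarray, lengths: np.ndarray, pos: int) -> int:
    i = int(np.searchsorted(src, pos, side="right")) - 1
    if i < 0:
        return int(dst[0])
    off = min(pos - src[i], lengths[i] - 1) if lengths[i] > 0 else 0
    return int(dst[i] + max(off, 0))


def _project_array(src: np.ndarray, dst: np.ndarray, lengths: np.ndarray, pos: np.ndarray) -> np.ndarray:
    pos = np.asarray(pos, dtype=np.int64)
    i = np.clip(np.searchsorted(src, pos, side="right") - 1, 0, len(src) - 1)
    off = np.clip(pos - src[i], 0, np.maximum(lengths[i] - 1, 0))
    return dst[i] + off


def _check_nonoverlap(variants: list[Variant], contig_len: int) -> None:
    prev_end = -1
    for v in variants:
        if v.position <= prev_end:
            raise ValueError(f"overlapping variants at position {v.position}")
        if v.position + len(v.ref) > contig_len:
            raise ValueError(f"variant at {v.position} exceeds contig")
        prev_end = v.position + len(v.ref) - 1


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()
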