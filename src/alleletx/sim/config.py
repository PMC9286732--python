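"""Configuration of the synthetic transcription-cycle generator.

All knobs that define the simulated study live here: the diploid variant
densities, the initiator-dinucleotide preference weights, the DNA-melting
(AT) coefficient, the pause energy rule, allelic effect-class proportions,
and the sequencing design (organs x reciprocal crosses x replicates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

CROSSES = ("A1xA2", "A2xA1")  # mother listed first
EFFECT_CLASSES = (
    "none",
    "abundance",
    "shape_single",
    "shape_multi",
    "termination",
    "imprinted",
)


@dataclass
class SimConfig:
    seed: int = 0
    n_loci: int = 60
    contig: str = "chrS"
    # diploid variation
    snp_density: float = 0.005          # per bp, background heterozygous SNPs
    indel_density: float = 3e-4         # per bp, background 1-5 bp indels
    # initiator preferences: Pol II initiates best at CA, then TA, TG, CG
    w_CA: float = 1.0
    w_TA: float = 0.5
    w_TG: float = 0.25
    w_CG: float = 0.1
    w_other: float = 0.05               # non-pyrimidine/purine initiators
    at_coefficient: float = 0.5         # exp(alpha * AT fraction of +/-5 bp)
    # pause energetics: Pol II stalls on a C just after a G-rich stretch
    pause_weight_c: float = 2.0         # bonus for C at the active site
    pause_weight_g: float = 0.25        # per G in the 10 bp upstream bubble
    # "energy": global argmax over offsets 20-60 (purely sequence-anchored);
    # "pic": fixed TSS offset in allele-local coordinates;
    # "constrained": argmax of the energy rule within a PIC-set window of
    # +/- pause_search_halfwidth around the planted offset (distance
    # anchoring dominates, sequence picks the exact base)
    pause_mode: str = "energy"
    pause_search_halfwidth: int = 2
    pause_offset_range: tuple[int, int] = (25, 55)
    pause_snp_prob: float = 0.0         # forced active-site C->D SNP on allele 2
    pause_indel_prob: float = 0.0       # forced indel between TSS and pause
    pause_indel_lengths: tuple[int, int] = (3, 8)
    initiator_snp_prob: float = 0.3     # maxTSS dinucleotide differs on allele 2
    # read simulation
    reads_per_tsc: float = 40.0         # mean tagged reads per TSC per sample
    tagging_prob: float = 0.5           # fraction of reads carrying a variant
    body_read_fraction: float = 0.4     # 3' ends spread over the gene body
    pause_jitter_p: float = 0.5         # geometric decay of 3'-end jitter
    pause_jitter_max: int = 4
    overdispersion: float = 0.0         # 0 -> Poisson; >0 -> negative binomial
    # study design
    organs: tuple[str, ...] = ("liver",)
    n_replicates: int = 2
    # allelic effects
    effect_proportions: dict = field(
        default_factory=lambda: {
            "none": 0.55,
            "abundance": 0.15,
            "shape_single": 0.08,
            "shape_multi": 0.07,
            "termination": 0.10,
            "imprinted": 0.05,
        }
    )
    abundance_ratio: float = 3.0        # allele-1 fold change at abundance loci
    imprinted_ratio: float = 4.0        # maternal fold change at imprinted loci
    shape_single_fold: float = 4.0      # one TSS shifted on allele 1
    shape_multi_fold: float = 2.0       # three TSSs shifted on allele 1
    termination_frac_range: tuple[float, float] = (0.2, 0.45)
    structure_change_prob: float = 0.5  # of termination loci: novel 3' exon
    stability_shift: float = 3.0        # allelic stability fold at changed loci
    mrna_depth: float = 0.5             # mRNA reads per transcription-rate unit
    # locus geometry
    unit_length_range: tuple[int, int] = (2000, 5000)
    slot_margin: int = 600

    # ------------------------------------------------------------------
    @property
    def slot_width(self) -> int:
        return 2 * (self.unit_length_range[1] + self.slot_margin)

    @property
    def contig_length(self) -> int:
        return self.slot_width * self.n_loci + 2 * self.slot_margin

    def validate(self) -> None:
        if self.contig_length < 10_000:
            raise ValueError("contig too short for requested loci")
        for name in ("w_CA", "w_TA", "w_TG", "w_CG", "w_other"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("tagging_prob", "body_read_fraction", "initiator_snp_prob",
                     "pause_snp_prob", "pause_indel_prob", "structure_change_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.pause_mode not in ("energy", "pic", "constrained"):
            raise ValueError("pause_mode must be 'energy', 'pic' or 'constrained'")
        lo, hi = self.pause_offset_range
        if not (20 <= lo <= hi <= 60):
            raise ValueError("pause offsets must lie in [20, 60]")
        total = sum(self.effect_proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("effect proportions must sum to 1")
        if set(self.effect_proportions) - set(EFFECT_CLASSES):
            raise ValueError("unknown effect class")

    def initiator_weights(self) -> dict[str, float]:
        return {"CA": self.w_CA, "TA": self.w_TA, "TG": self.w_TG, "CG": self.w_CG}
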