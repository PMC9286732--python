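"""Analysis configuration: every tunable threshold of the pipeline.

Defaults mirror the published analysis of F1-hybrid nascent transcription:
5-read TSS support, 60 bp TSC merging, 10% discovery / 90% background FDR,
5/10 bp SNP profile bins, the -35..-20 TATA window with a log-odds cutoff
of 3, the 10-50 bp TSS->pause pairing window, pause context blocks, the
final-10% / 50%-length termination rules, a 10 kb mRNA upstream window,
a 10-read stability filter and a 500 bp gene-body skip.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml


@dataclass
class AnalysisConfig:
    min_tss_reads: int = 5
    tsc_merge_gap: int = 60
    fdr_abundance: float = 0.10
    fdr_background: float = 0.90
    snp_profile_bin: int = 5
    snp_test_bin: int = 10
    snp_enrichment_fdr: float = 0.05
    tata_window: tuple[int, int] = (-35, -20)
    tata_score_threshold: float = 3.0
    shooting_window: int = 20
    pause_pair_window: tuple[int, int] = (10, 50)
    pause_min_allelic_reads: int = 5
    pause_ratio_bounds: tuple[float, float] = (0.5, 2.0)
    pause_blocks: tuple[tuple[int, int], ...] = ((-20, -11), (-10, -1), (1, 10))
    termination_final_fraction: float = 0.10
    termination_length_cap: float = 0.50
    rnaseq_upstream_window: int = 10_000
    stability_min_reads: int = 10
    gene_body_skip: int = 500
    hmm_tau_grid: tuple[float, ...] = (1e-5, 1e-4, 1e-3, 1e-2)
    hmm_rho: float = 0.9

    def __post_init__(self):
        for name in ("tata_window", "pause_pair_window", "pause_ratio_bounds"):
            lo, hi = getattr(self, name)
            if lo >= hi:
                raise ValueError(f"{name} must be well-ordered")
        for name in ("fdr_abundance", "fdr_background", "snp_enrichment_fdr"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, val in raw.items():
            if isinstance(val, list):
                raw[key] = tuple(tuple(v) if isinstance(v, list) else v for v in val)
        return cls(**raw)
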