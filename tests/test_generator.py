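"""Planted truth and read/mRNA simulation."""

import numpy as np
import pytest

from alleletx.sim import (
    EFFECT_CLASSES,
    SimConfig,
    generate_genome_pair,
    oriented_window,
    pause_energy_argmax,
    plant_truth,
    simulate_mrna_counts,
    simulate_read_ends,
)


def _cfg(**kw):
    base = dict(seed=21, n_loci=10)
    base.update(kw)
    return SimConfig(**base)


def _uniform_props(**kw):
    props = {c: 0.0 for c in EFFECT_CLASSES}
    props.update(kw)
    return props


class TestPlantedTruth:
    def test_equal_weights_and_no_at_effect_give_equal_rates_at_snp_free_loci(self):
        cfg = _cfg(w_CA=1, w_TA=1, w_TG=1, w_CG=1, at_coefficient=0.0,
                   snp_density=0.0, indel_density=0.0, initiator_snp_prob=0.0,
                   effect_proportions=_uniform_props(none=1.0))
        truth = plant_truth(generate_genome_pair(cfg), cfg)
        for locus in truth.loci:
            for tss in locus.tss:
                assert tss.rate["A1"] == pytest.approx(tss.rate["A2"])

    def test_initiator_snp_sets_rate_ratio_to_weight_ratio(self):
        cfg = _cfg(initiator_snp_prob=1.0, at_coefficient=0.0,
                   effect_proportions=_uniform_props(none=1.0))
        genome = generate_genome_pair(cfg)
        truth = plant_truth(genome, cfg)
        w = cfg.initiator_weights()
        seen = 0
        for locus in truth.loci:
            t = locus.max_tss
            if t.dinuc["A1"] == t.dinuc["A2"]:
                continue
            seen += 1
            expected = w[t.dinuc["A1"]] / w[t.dinuc["A2"]]
            assert t.rate["A1"] / t.rate["A2"] == pytest.approx(expected)
        assert seen > 0

    def test_pause_argmax_matches_brute_force_on_each_allele(self):
        cfg = _cfg(pause_mode="energy", pause_snp_prob=0.5, pause_indel_prob=0.5)
        genome = generate_genome_pair(cfg)
        truth = plant_truth(genome, cfg)
        for locus in truth.loci:
            for allele, seq in (("A1", genome.seq1), ("A2", genome.seq2)):
                tss = locus.max_tss.pos_a1 if allele == "A1" else locus.max_tss.pos_a2_local
                s = oriented_window(seq, tss, 0, 61, locus.strand)
                scores = [
                    cfg.pause_weight_c * (s[o] == "C")
                    + cfg.pause_weight_g * s[o - 10 : o].count("G")
                    for o in range(20, 61)
                ]
                brute = 20 + int(np.argmax(scores))
                assert locus.pause_offset_obs[allele] == brute
                assert 20 <= brute <= 60

    def test_termination_truth_respects_length_cap(self):
        cfg = _cfg(effect_proportions=_uniform_props(termination=1.0))
        truth = plant_truth(generate_genome_pair(cfg), cfg)
        for locus in truth.loci:
            diff = locus.plan.unit_length - locus.plan.short_unit_length
            assert 0 < diff <= 0.5 * locus.plan.unit_length


class TestReadSimulation:
    def test_fixed_seed_identical_read_table(self):
        cfg = _cfg()
        truth = plant_truth(generate_genome_pair(cfg), cfg)
        a, b = simulate_read_ends(truth), simulate_read_ends(truth)
        assert a.equals(b)

    def test_tagging_zero_leaves_everything_untagged(self):
        cfg = _cfg(tagging_prob=0.0)
        truth = plant_truth(generate_genome_pair(cfg), cfg)
        reads = simulate_read_ends(truth)
        assert (reads["allele"] == "untagged").all()

    def test_allele_counts_conserve_totals(self, mixed_sim):
        _, _, _, reads = mixed_sim
        per_locus = reads.groupby("locus").size()
        tagged = reads[reads["allele"] != "untagged"].groupby("locus").size()
        untagged = reads[reads["allele"] == "untagged"].groupby("locus").size()
        total = tagged.reindex(per_locus.index, fill_value=0) + untagged.reindex(
            per_locus.index, fill_value=0
        )
        assert (total == per_locus).all()

    def test_strand_invariant_of_read_ends(self, mixed_sim):
        _, _, _, reads = mixed_sim
        plus = reads[reads["strand"] == "+"]
        minus = reads[reads["strand"] == "-"]
        assert (plus["five_prime"] <= plus["three_prime"]).all()
        assert (minus["three_prime"] <= minus["five_prime"]).all()

    def test_poisson_mean_recovered(self):
        """Mean simulated count per locus within 3 SE of the configured depth."""
        cfg = _cfg(n_loci=80, tagging_prob=1.0, n_replicates=1)
        truth = plant_truth(generate_genome_pair(cfg), cfg)
        reads = simulate_read_ends(truth)
        counts = reads.groupby(["locus", "cross"]).size()
        mean = counts.mean()
        se = counts.std() / np.sqrt(len(counts))
        assert abs(mean - cfg.reads_per_tsc) <= 3 * se + 1e-9

    def test_initiator_frequencies_converge_to_weights(self):
        """Empirical 5'-end share of each planted TSS tracks its rate."""
        cfg = _cfg(n_loci=25, reads_per_tsc=300, body_read_fraction=0.0)
        truth = plant_truth(generate_genome_pair(cfg), cfg)
        reads = simulate_read_ends(truth)
        tagged = reads[reads["allele"] == "A1"]
        for locus in truth.loci[:10]:
            lam = np.array([t.rate["A1"] for t in locus.tss])
            expect = lam / lam.sum()
            obs = np.array(
                [
                    (tagged["five_prime"] == t.pos_a1).sum()
                    for t in locus.tss
                ],
                dtype=float,
            )
            if obs.sum() < 50:
                continue
            frac = obs / obs.sum()
            se = np.sqrt(expect * (1 - expect) / obs.sum())
            assert np.all(np.abs(frac - expect) <= 4 * se + 0.02)


class TestMrnaSimulation:
    def test_novel_exon_silent_on_short_allele(self):
        cfg = _cfg(effect_proportions=_uniform_props(termination=1.0),
                   structure_change_prob=1.0)
        truth = plant_truth(generate_genome_pair(cfg), cfg)
        mrna = simulate_mrna_counts(truth)
        novel = mrna[mrna["exon_kind"] == "novel"]
        assert len(novel) > 0
        short = {l.gene_id: ("A2" if l.plan.long_allele == "A1" else "A1") for l in truth.loci}
        for row in novel.itertuples():
            assert getattr(row, short[row.gene]) == 0

    def test_stability_multiplier_scales_mrna_ratio(self):
        cfg = _cfg(n_loci=40, effect_proportions=_uniform_props(termination=1.0),
                   structure_change_prob=1.0, stability_shift=2.0, mrna_depth=5.0)
        truth = plant_truth(generate_genome_pair(cfg), cfg)
        mrna = simulate_mrna_counts(truth)
        shared = mrna[mrna["exon_kind"] == "shared"].groupby("gene")[["A1", "A2"]].sum()
        ratios = []
        for locus in truth.loci:
            s1, s2 = locus.plan.stability
            row = shared.loc[locus.gene_id]
            ratios.append((row["A1"] / max(row["A2"], 1)) / (s1 / s2))
        # after dividing out the planted stability, ratios center on 1
        assert abs(np.median(ratios) - 1.0) < 0.15
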