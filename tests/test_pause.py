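"""Pause-position determinants."""

import math

import numpy as np
import pytest

import oracles

from alleletx.pause import (
    classify_pause_explanations,
    indel_offset_analysis,
    pause_distance_comparisons,
    pause_sequence_context,
    same_tss_diff_pause_sets,
)
from alleletx.sim.genome import GenomePair, Variant
from alleletx.stats import ShapeTestResult
from alleletx.tss import PausePair


def _pair(region, tss, pause1, pause2, strand="+"):
    d1 = pause1 - tss if strand == "+" else tss - pause1
    d2 = pause2 - tss if strand == "+" else tss - pause2
    return PausePair(
        region, strand, {"A1": tss, "A2": tss}, {"A1": pause1, "A2": pause2},
        {"A1": float(d1), "A2": float(d2)}, True,
    )


def _shape(rid, q):
    r = ShapeTestResult(unit_id=rid, d=0.5, p_value=0.01)
    r.q_value = q
    return r


class TestTestControlSets:
    def test_partition_rules(self):
        pairs = [
            _pair("sig_diff", 100, 140, 145),
            _pair("sig_same", 100, 140, 140),
            _pair("mid", 100, 140, 145),
            _pair("ctrl_same", 100, 140, 140),
            _pair("ratio_out", 100, 140, 145),
        ]
        shapes = [
            _shape("sig_diff", 0.05), _shape("sig_same", 0.05),
            _shape("mid", 0.5), _shape("ctrl_same", 0.95), _shape("ratio_out", 0.05),
        ]
        reads = {
            "sig_diff": (20, 20), "sig_same": (20, 20), "mid": (20, 20),
            "ctrl_same": (20, 20), "ratio_out": (60, 10),
        }
        test, ctrl = same_tss_diff_pause_sets(pairs, shapes, reads)
        assert [p.region_id for p in test] == ["sig_diff"]
        assert [p.region_id for p in ctrl] == ["ctrl_same"]

    def test_min_allelic_reads(self):
        pairs = [_pair("r", 100, 140, 145)]
        test, ctrl = same_tss_diff_pause_sets(pairs, [_shape("r", 0.05)], {"r": (4, 20)})
        assert test == [] and ctrl == []


class TestIndelAnalysis:
    def test_deletion_between_tss_and_pause_sets_signed_length(self):
        seq = "A" * 400
        g = GenomePair.from_allele1("c", seq, [Variant(119, seq[119:123], seq[119])])
        # allele 2 misses 3 bp between TSS (100) and pause; its distance-
        # anchored pause projects 3 bp further on allele 1, so the deleted
        # allele is the (projected) long allele: negative sign
        pair = _pair("r", 100, 140, 143)
        df, _ = indel_offset_analysis([pair], [], g)
        row = df.iloc[0]
        assert row["short_allele"] == "A1"
        assert row["indel_length"] == -3
        assert row["pause_diff"] == 3.0

    def test_no_indel_leaves_zero_length(self):
        g = GenomePair.from_allele1("c", "A" * 400, [])
        df, _ = indel_offset_analysis([_pair("r", 100, 140, 141)], [], g)
        assert df.iloc[0]["indel_length"] == 0


class TestSequenceContext:
    def test_g_rich_bubble_then_c(self):
        seq = list("A" * 200)
        seq[120:130] = "G" * 10
        seq[130] = "C"
        g = GenomePair.from_allele1("c", "".join(seq), [])
        ctx = pause_sequence_context([(130, "+")], g)
        assert ctx["modal_pause_base"] == "C"
        assert ctx["g_content"]["block2"][0] == 1.0
        assert ctx["g_content"]["block1"][0] == 0.0

    def test_uniform_genome_shows_no_block_difference(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), size=40_000))
        g = GenomePair.from_allele1("c", seq, [])
        sites = [(int(p), "+") for p in rng.integers(100, 39_900, size=300)]
        ctx = pause_sequence_context(sites, g)
        assert ctx["comparisons"]["block2_vs_block1"] > 0.01

    def test_edge_sites_dropped(self):
        g = GenomePair.from_allele1("c", "A" * 100, [])
        with pytest.raises(ValueError):
            pause_sequence_context([(5, "+")], g)


class TestExplanations:
    def test_active_site_snp_tag(self):
        seq = "A" * 400
        g = GenomePair.from_allele1("c", seq, [Variant(140, "A", "G")])
        pair = _pair("r", 100, 140, 145)      # short allele A1, pause at 140
        recs, fractions = classify_pause_explanations([pair], g)
        assert recs[0].tags == ["active_site_snp"]
        assert fractions["active_site_snp"] == 1.0

    def test_no_variant_is_unexplained_and_fractions_partition(self):
        g = GenomePair.from_allele1("c", "A" * 400, [])
        recs, fractions = classify_pause_explanations([_pair("r", 100, 140, 145)], g)
        assert recs[0].explanation == "unexplained"
        cats = ["active_site_snp", "bubble_snp", "downstream_snp",
                "indel_tss_to_pause", "multiple", "unexplained"]
        assert sum(fractions[c] for c in cats) == pytest.approx(1.0)

    def test_two_classes_become_multiple(self):
        seq = "A" * 400
        g = GenomePair.from_allele1(
            "c", seq, [Variant(135, "A", "G"), Variant(145, "A", "G")]
        )
        recs, _ = classify_pause_explanations([_pair("r", 100, 140, 147)], g)
        assert recs[0].explanation == "multiple"


class TestDistanceComparisons:
    def test_full_subset_gives_p_one_and_ks_matches_enumeration(self):
        g = GenomePair.from_allele1("c", "A" * 1000, [])
        recs, _ = classify_pause_explanations(
            [_pair(f"r{i}", 100, 140, 140 + d) for i, d in enumerate((3, 5, 20, 30, 40))], g
        )
        for i, tag in enumerate(["active_site_snp"] * 2 + ["indel_tss_to_pause"] * 3):
            recs[i].tags = [tag]
        out = pause_distance_comparisons(recs)
        c_row = out[out["subset"] == "c_snp"].iloc[0]
        d0, p0 = oracles.ks_permutation([3, 5], [20, 30, 40])
        assert c_row["d"] == pytest.approx(d0)
        assert c_row["median"] < c_row["median_rest"]

    def test_empty_subset_sentinel(self):
        out = pause_distance_comparisons([])
        assert out["p"].isna().all()
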