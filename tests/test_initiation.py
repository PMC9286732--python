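"""Sequence determinants of initiation."""

import math

import numpy as np
import pytest

from alleletx.initiation import (
    MarkovBackground,
    MaxTssSite,
    Pwm,
    base_composition_and_at,
    bundled_pwms,
    dinucleotide_hierarchy,
    initiator_dinuc,
    shooting_gallery,
    shooting_ratio,
    snp_positional_profile,
    tata_association,
)
from alleletx.sim.genome import GenomePair, Variant


def _genome(seq1, variants=()):
    return GenomePair.from_allele1("c", seq1, list(variants))


def _flat_genome(length=400, fill="A"):
    return fill * length


class TestHierarchy:
    def test_ca_to_ta_category_and_ratio(self):
        seq = list(_flat_genome())
        seq[99:101] = "CA"          # allele-1 initiator at pos 100
        g = _genome("".join(seq), [Variant(99, "C", "T")])  # allele 2: TA
        sites = [MaxTssSite(100, "+", 20, 10)]
        ratios, _ = dinucleotide_hierarchy(sites, g)
        assert ratios == {"CA>TA": [1.0]}

    def test_no_initiator_change_excluded(self):
        seq = list(_flat_genome())
        seq[99:101] = "CA"
        g = _genome("".join(seq))
        ratios, _ = dinucleotide_hierarchy([MaxTssSite(100, "+", 20, 10)], g)
        assert ratios == {}

    def test_minus_strand_initiator_read_from_complement(self):
        seq = list(_flat_genome(fill="G"))
        # - strand TSS at 100: initiator = revcomp(seq[100:102])
        seq[100] = "T"  # base at offset 0 -> complement A
        seq[101] = "G"  # base at offset -1 -> complement C
        g = _genome("".join(seq))
        assert initiator_dinuc(g, 100, "-", "A1") == "CA"


class TestSnpProfile:
    def test_spike_at_anchor_detected(self):
        seq = _flat_genome(2000)
        variants = [Variant(p, "A", "G") for p in (500, 700, 900)]
        g = _genome(seq, variants)
        test = [(500, "+"), (700, "+"), (900, "+")]
        ctrl = [(1300, "+"), (1500, "+"), (1700, "+")]
        prof = snp_positional_profile(test, ctrl, g, window=50)
        row = prof[(prof["bin_start"] == 0)]
        assert row["mean_test"].iloc[0] == 1.0
        assert row["mean_control"].iloc[0] == 0.0

    def test_minus_strand_offset_flip(self):
        seq = _flat_genome(2000)
        g = _genome(seq, [Variant(497, "A", "G")])  # 3 bp 5'-ward of a - strand anchor at 500
        prof = snp_positional_profile([(500, "-")], [(1500, "-")], g, window=20)
        hit = prof[(prof["mean_test"] > 0)]
        assert list(hit["bin_start"]) == [0]  # offset +3 -> bin [0,5)
        prof_plus = snp_positional_profile([(500, "+")], [(1500, "+")], g, window=20)
        hit = prof_plus[(prof_plus["mean_test"] > 0)]
        assert list(hit["bin_start"]) == [-5]

    def test_empty_control_rejected(self):
        g = _genome(_flat_genome())
        with pytest.raises(ValueError):
            snp_positional_profile([(100, "+")], [], g)


class TestBaseComposition:
    def test_at_difference_of_one(self):
        # allele1 A-rich, allele2 G at a window of offsets; high allele = A1
        seq = _flat_genome(400)
        variants = [Variant(p, "A", "G") for p in range(110, 115)]
        g = _genome(seq, variants)
        site = MaxTssSite(100, "+", 30, 10)
        out = base_composition_and_at([site], g, window=20, at_bin=5)
        win = out["at_windows"]
        row = win[win["bin_start"] == 10]
        assert row["at_diff"].iloc[0] == pytest.approx(1.0)

    def test_masked_initiator_positions_never_contribute(self):
        seq = _flat_genome(400)
        g = _genome(seq, [Variant(100, "A", "G")])  # SNP only at offset 0
        out = base_composition_and_at([MaxTssSite(100, "+", 30, 10)], g, window=20)
        assert out["at_windows"]["at_diff"].abs().max() == 0.0
        assert all(len(x) == 0 for x in out["at_gc_offsets"])

    def test_equal_depth_sites_excluded(self):
        g = _genome(_flat_genome(400))
        with pytest.raises(ValueError):
            base_composition_and_at([MaxTssSite(100, "+", 10, 10)], g)


class TestTata:
    def test_uniform_pwm_scores_zero_against_uniform_background(self):
        probs = np.full((6, 4), 0.25)
        pwm = Pwm("flat", probs, threshold=3.0)
        rng = np.random.default_rng(0)
        bg = MarkovBackground("".join(rng.choice(list("ACGT"), size=120_000)))
        assert pwm.score("ACGTACGTACGTACGT", bg) == pytest.approx(0.0, abs=0.15)

    def test_perfect_match_scores_sum_of_log_odds(self):
        pwms = bundled_pwms()
        strict = pwms["tata_strict"]
        rng = np.random.default_rng(1)
        bg = MarkovBackground("".join(rng.choice(list("ACGT"), size=120_000)))
        s = strict.score("TATAAA", bg)
        expected = sum(math.log2(strict.probs[j].max() / 0.25) for j in range(6))
        assert s == pytest.approx(expected, rel=0.1)

    def test_constant_score_difference_gives_sentinel(self):
        g = _genome(_flat_genome(600))
        sites = [MaxTssSite(300 + i, "+", 10 + i, 10, f"s{i}") for i in range(4)]
        pwm = bundled_pwms()["tata_soft"]
        table, r, p = tata_association(sites, g, pwm)
        # identical alleles -> every d_score = 0 -> degenerate correlation
        assert math.isnan(r) and math.isnan(p)

    def test_tata_creating_snp_associates_with_usage(self):
        rng = np.random.default_rng(3)
        seq = list("".join(rng.choice(list("ACGT"), size=5000)))
        sites, variants = [], []
        for i, anchor in enumerate(range(300, 4700, 200)):
            seq[anchor - 30 : anchor - 24] = list("TATAAA")
            if i % 2 == 0:
                variants.append(Variant(anchor - 30, seq[anchor - 30], "G"))  # break TATA on A2
                sites.append(MaxTssSite(anchor, "+", 40, 10, f"s{i}"))
            else:
                sites.append(MaxTssSite(anchor, "+", 20, 20, f"s{i}"))
        g = _genome("".join(seq), variants)
        table, r, p = tata_association(sites, g, bundled_pwms()["tata_strict"])
        assert len(table) > 5
        assert r > 0.5 and p < 0.05


class TestShootingGallery:
    def test_ratio_example(self):
        assert shooting_ratio(9, 3, pseudocount=0) == pytest.approx(3.0)

    def test_site_partition_and_candidate_scan(self):
        seq = list(_flat_genome(600, fill="G"))
        seq[299:301] = "CA"          # test-site initiator on allele 1
        seq[309:311] = "TA"          # candidate initiator at +10 on both alleles
        g = _genome("".join(seq), [Variant(300, "A", "G")])  # allele2: CG at maxTSS
        sites = [MaxTssSite(300, "+", 30, 6, "t")]
        counts = {(310, "+"): (2, 9)}
        table = shooting_gallery(sites, g, counts, window=20, pseudocount=0.5)
        assert set(table["group"]) == {"test"}
        row = table[table["offset"] == 10].iloc[0]
        assert row["dinuc"] == "TA"
        assert row["ratio"] == pytest.approx((9 + 0.5) / (2 + 0.5))

    def test_central_max_tss_excluded(self):
        seq = list(_flat_genome(600, fill="G"))
        seq[299:301] = "CA"
        g = _genome("".join(seq), [Variant(300, "A", "G")])
        table = shooting_gallery([MaxTssSite(300, "+", 30, 6, "t")], g, {}, window=20)
        assert (table["offset"] != 0).all()
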