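"""TSS/TSC/TSR calling and pause pairing."""

import pandas as pd
import pytest

from alleletx.tss import (
    CandidateRegion,
    SiteCounts,
    call_max_pause,
    call_tss,
    cluster_tsc,
    assign_tsr,
    make_base_counts,
    pair_tss_pause,
)


def _reads(rows):
    cols = ["contig", "five_prime", "three_prime", "strand", "allele", "organ", "cross", "replicate"]
    return pd.DataFrame([dict(zip(cols, r)) for r in rows])


def _counts(pos_counts, strand="+", end_type="five_prime", contig="c"):
    rows = []
    for pos, (a1, a2, un) in pos_counts.items():
        rows.append(
            {"contig": contig, "strand": strand, "pos": pos, "A1": a1, "A2": a2,
             "untagged": un, "all": a1 + a2 + un}
        )
    df = pd.DataFrame(rows).sort_values("pos").reset_index(drop=True)
    return SiteCounts(df, end_type)


class TestBaseCounts:
    def test_five_prime_counting_and_allele_split(self):
        reads = _reads([
            ("c", 100, 140, "+", "A1", "o", "A1xA2", 1),
            ("c", 100, 141, "+", "untagged", "o", "A1xA2", 1),
            ("c", 100, 150, "-", "A2", "o", "A1xA2", 1),
        ])
        counts = make_base_counts(reads, "five_prime")
        plus = counts.df[counts.df["strand"] == "+"]
        assert plus["all"].sum() == 2 and plus["A1"].sum() == 1 and plus["untagged"].sum() == 1
        minus = counts.df[counts.df["strand"] == "-"]
        assert minus["A2"].sum() == 1  # strands never pooled

    def test_every_read_counted_once(self, mixed_sim):
        _, _, _, reads = mixed_sim
        c5 = make_base_counts(reads, "five_prime")
        c3 = make_base_counts(reads, "three_prime")
        assert c5.df["all"].sum() == len(reads) == c3.df["all"].sum()


class TestCallTss:
    def test_threshold_and_region_containment(self):
        counts = _counts({50: (3, 2, 0), 60: (2, 2, 0), 500: (9, 9, 0)})
        tss = call_tss(counts, [CandidateRegion("c", 40, 80)], min_reads=5)
        assert list(tss["pos"]) == [50]  # 60 is under threshold, 500 outside

    def test_min_reads_one_keeps_every_covered_base(self):
        counts = _counts({50: (1, 0, 0), 51: (0, 1, 0)})
        tss = call_tss(counts, [CandidateRegion("c", 0, 100)], min_reads=1)
        assert list(tss["pos"]) == [50, 51]

    def test_no_regions_warns_and_returns_empty(self, caplog):
        counts = _counts({50: (5, 5, 0)})
        tss = call_tss(counts, [], min_reads=5)
        assert tss.empty


class TestClusterTsc:
    def test_sixty_bp_chaining(self):
        counts = _counts({100: (5, 0, 0), 130: (5, 0, 0), 200: (5, 0, 0)})
        tss = call_tss(counts, [CandidateRegion("c", 0, 300)], min_reads=5)
        tscs = cluster_tsc(tss, merge_gap=60)
        assert [(t.start, t.end) for t in tscs] == [(100, 131), (200, 201)]

    def test_tied_max_tss_all_retained(self):
        counts = _counts({100: (4, 3, 0), 130: (5, 2, 0)})
        tss = call_tss(counts, [CandidateRegion("c", 0, 300)], min_reads=5)
        (tsc,) = cluster_tsc(tss)
        assert tsc.max_tss == [100, 130]
        assert tsc.max_tss_primary == 100

    def test_clustering_idempotent_and_order_invariant(self):
        counts = _counts({100: (5, 0, 0), 120: (6, 0, 0), 300: (7, 0, 0)})
        tss = call_tss(counts, [CandidateRegion("c", 0, 400)], min_reads=5)
        a = cluster_tsc(tss)
        b = cluster_tsc(tss.sample(frac=1, random_state=1))
        assert [(t.start, t.end) for t in a] == [(t.start, t.end) for t in b]

    def test_assign_tsr_groups_by_region_and_strand(self):
        counts = _counts({100: (5, 0, 0), 200: (5, 0, 0)})
        tss = call_tss(counts, [CandidateRegion("c", 0, 300, "r0")], min_reads=5)
        tsrs = assign_tsr(cluster_tsc(tss))
        assert set(tsrs) == {("r0", "+")} and len(tsrs[("r0", "+")]) == 2


class TestMaxPause:
    def test_modal_base(self):
        counts = _counts({140: (9, 0, 0), 141: (2, 0, 0)}, end_type="three_prime")
        reg = CandidateRegion("c", 100, 200)
        assert call_max_pause(counts, reg, "A1", "+") == 140

    def test_tie_takes_five_prime_most_per_strand(self):
        counts = _counts({140: (5, 5, 0), 145: (5, 5, 0)}, end_type="three_prime")
        reg = CandidateRegion("c", 100, 200)
        assert call_max_pause(counts, reg, "A1", "+") == 140
        counts_m = _counts({140: (5, 5, 0), 145: (5, 5, 0)}, strand="-", end_type="three_prime")
        assert call_max_pause(counts_m, reg, "A1", "-") == 145

    def test_insufficient_reads_returns_none(self):
        counts = _counts({140: (4, 9, 0)}, end_type="three_prime")
        assert call_max_pause(counts, CandidateRegion("c", 100, 200), "A1", "+") is None


class TestPairTssPause:
    @pytest.mark.parametrize(
        "strand,tss,pause,dist,valid",
        [("+", 100, 140, 40.0, True), ("+", 100, 160, 60.0, False), ("-", 200, 170, 30.0, True)],
    )
    def test_distance_window(self, strand, tss, pause, dist, valid):
        pair = pair_tss_pause(
            "r", strand, {"A1": tss, "A2": tss}, {"A1": pause, "A2": pause}, (10, 50)
        )
        assert pair.distance["A1"] == dist and pair.valid is valid

    def test_missing_pause_flagged_not_raised(self):
        pair = pair_tss_pause("r", "+", {"A1": 100, "A2": 100}, {"A1": 140, "A2": None})
        assert not pair.valid and "A2" in pair.reason
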