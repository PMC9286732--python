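"""Allelic block HMM, domain merging and gene-level classification."""

import math
from itertools import product

import numpy as np
import pytest
from scipy import stats as sps

from alleletx.hmm import (
    Domain,
    HmmBlock,
    HmmConfig,
    adjacency_sharing_test,
    classify_gene_allelic_state,
    count_genes_per_domain,
    hmm_call_blocks,
    merge_blocks_to_domains,
    select_tau,
    viterbi_states,
)


def _brute_force_path(a1, a2, cfg):
    """Exhaustive maximization over all 3^T state paths."""
    n = np.asarray(a1) + np.asarray(a2)
    probs = [0.5, cfg.rho, 1 - cfg.rho]
    log_tau = math.log(cfg.tau)
    log_stay = math.log(1 - 2 * cfg.tau)
    best, best_path = -np.inf, None
    for path in product(range(3), repeat=len(a1)):
        ll = log_stay if path[0] == 0 else log_tau
        for t, s in enumerate(path):
            ll += sps.binom.logpmf(a1[t], n[t], probs[s])
            if t:
                ll += log_stay if s == path[t - 1] else log_tau
        if ll > best:
            best, best_path = ll, path
    return np.array(best_path)


class TestViterbi:
    def test_balanced_positions_give_zero_blocks(self):
        pos = np.arange(10) * 100
        a = np.full(10, 5)
        assert hmm_call_blocks(pos, a, a, HmmConfig(tau=1e-3)) == []

    def test_planted_run_recovered_exactly(self):
        pos = np.arange(20) * 50
        a1 = np.array([5] * 5 + [9] * 10 + [5] * 5)
        a2 = np.array([5] * 5 + [1] * 10 + [5] * 5)
        (block,) = hmm_call_blocks(pos, a1, a2, HmmConfig(tau=1e-3), "c", "+")
        assert (block.start, block.end) == (pos[5], pos[14] + 1)
        assert block.direction == "A1"
        assert block.p_value < 1e-10

    def test_tau_zero_forbids_blocks(self):
        pos = np.arange(10) * 10
        a1 = np.full(10, 9)
        a2 = np.full(10, 1)
        assert hmm_call_blocks(pos, a1, a2, HmmConfig(tau=0.0)) == []

    @pytest.mark.parametrize("trial", range(8))
    def test_viterbi_equals_exhaustive_path_search(self, trial):
        rng = np.random.default_rng([31, trial])
        T = int(rng.integers(5, 9))
        a1 = rng.integers(0, 10, size=T)
        a2 = rng.integers(0, 10, size=T)
        keep = (a1 + a2) > 0
        a1, a2 = a1[keep], a2[keep]
        if a1.size < 2:
            return
        cfg = HmmConfig(tau=float(rng.choice([1e-3, 1e-2, 0.05])))
        assert np.array_equal(viterbi_states(a1, a2, cfg), _brute_force_path(a1, a2, cfg))


class TestSelectTau:
    def test_degenerate_grid(self):
        blocks = {1e-4: []}
        assert select_tau(blocks, [((0, 10), False)]) == 1e-4

    def test_prefers_tau_matching_reference_labels(self):
        good = [HmmBlock("c", "+", 100, 200, "A1", 50, 5)]
        blocks = {1e-5: [], 1e-4: good, 1e-3: good + [HmmBlock("c", "+", 400, 500, "A1", 9, 5)]}
        ref = [((100, 200), True), ((400, 500), False)]
        assert select_tau(blocks, ref) == 1e-4

    def test_all_equal_scores_take_smallest_tau(self):
        blocks = {1e-5: [], 1e-4: [], 1e-3: []}
        assert select_tau(blocks, [((0, 10), True)]) == 1e-5

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError):
            select_tau({1e-4: []}, [])


def _block(start, end, direction, cross, organ="liver", p=1e-6):
    return HmmBlock("c", "+", start, end, direction, 90, 10, p, organ, cross)


class TestDomains:
    def test_same_strain_both_crosses_is_strain_effect(self):
        doms = merge_blocks_to_domains([_block(0, 100, "A1", "A1xA2"), _block(0, 100, "A1", "A2xA1")])
        assert [d.domain_class for d in doms] == ["strain_effect"]
        assert doms[0].direction == "A1"

    def test_same_parent_is_imprinted(self):
        doms = merge_blocks_to_domains([_block(0, 100, "A1", "A1xA2"), _block(0, 100, "A2", "A2xA1")])
        assert [d.domain_class for d in doms] == ["imprinted"]
        assert doms[0].direction == "maternal"

    def test_single_cross_direction_raises(self):
        with pytest.raises(ValueError):
            merge_blocks_to_domains([_block(0, 100, "A1", "A1xA2")])

    def test_inconsistent_replicate_direction_dropped(self):
        blocks = [_block(0, 100, "A1", "A1xA2"), _block(0, 100, "A1", "A2xA1")]
        reps = {
            ("liver", "A1xA2", 1): [((0, 100), "A1", 0.001)],
            ("liver", "A1xA2", 2): [((0, 100), "A2", 0.001)],
            ("liver", "A2xA1", 1): [((0, 100), "A1", 0.001)],
            ("liver", "A2xA1", 2): [((0, 100), "A1", 0.001)],
        }
        assert merge_blocks_to_domains(blocks, reps) == []

    def test_cross_organ_merge_records_organs(self):
        blocks = [
            _block(0, 100, "A1", "A1xA2", "liver"),
            _block(0, 100, "A1", "A2xA1", "liver"),
            _block(50, 150, "A1", "A1xA2", "brain"),
            _block(50, 150, "A1", "A2xA1", "brain"),
        ]
        (dom,) = merge_blocks_to_domains(blocks)
        assert dom.organs == ["brain", "liver"] and (dom.start, dom.end) == (0, 150)


class TestGeneState:
    @pytest.mark.parametrize(
        "c1,c2,expected",
        [
            ((80, 20), (80, 20), "strain"),
            ((80, 20), (20, 80), "imprinted"),
        ],
    )
    def test_direction_logic(self, c1, c2, expected):
        counts = {"A1xA2": c1, "A2xA1": c2}
        qs = {"A1xA2": 0.01, "A2xA1": 0.01}
        assert classify_gene_allelic_state(counts, qs) == expected

    def test_non_significant_is_none(self):
        counts = {"A1xA2": (55, 45), "A2xA1": (55, 45)}
        qs = {"A1xA2": 0.5, "A2xA1": 0.5}
        assert classify_gene_allelic_state(counts, qs) == "none"


class TestAdjacency:
    def test_toy_table_matches_fisher_oracle(self):
        import oracles

        genes = (
            [(f"s{i}", 0.01) for i in range(10)]
            + [(f"b{i}", 0.95) for i in range(10)]
        )
        neighbor = {}
        for i in range(10):
            neighbor[f"s{i}"] = f"s{(i + 1) % 10}" if i < 8 else "b0"
            neighbor[f"b{i}"] = f"b{(i + 1) % 10}" if i < 7 else "s0"
        _, p = adjacency_sharing_test(genes, neighbor)
        assert p == pytest.approx(oracles.fisher_two_sided(8, 2, 3, 7), abs=1e-12)

    def test_independence_gives_or_near_one(self):
        rng = np.random.default_rng(5)
        genes = [(f"g{i}", float(rng.choice([0.01, 0.95]))) for i in range(4000)]
        neighbor = {f"g{i}": f"g{i + 1}" for i in range(3999)}
        odds, p = adjacency_sharing_test(genes, neighbor)
        assert 0.7 < odds < 1.4
        assert p > 0.01

    def test_degenerate_stratum_gives_sentinel(self):
        genes = [("a", 0.01), ("b", 0.02)]
        odds, p = adjacency_sharing_test(genes, {"a": "b", "b": "a"})
        assert math.isnan(p)


class TestGenesPerDomain:
    def test_overlap_bookend_and_strand_rules(self):
        dom = Domain("c", 0, 1000, "strain_effect", "A1")
        ann_overlap = [("c", 100, 300, "+"), ("c", 250, 400, "+")]
        assert count_genes_per_domain([dom], ann_overlap) == [1]
        ann_bookend = [("c", 100, 200, "+"), ("c", 200, 300, "+")]
        assert count_genes_per_domain([dom], ann_bookend) == [1]
        ann_opposite = [("c", 100, 300, "+"), ("c", 250, 400, "-")]
        assert count_genes_per_domain([dom], ann_opposite) == [2]
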