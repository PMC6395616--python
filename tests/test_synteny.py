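"""Tandem classification, anchor chaining, block filtering and depth."""

import numpy as np
import pytest

from oracles import oracle_best_chain, oracle_tandem_arrays
from paleofrac.io_formats import GeneTable, HitRecord
from paleofrac.synteny import (
    AnchorPair,
    ChainParams,
    SyntenicBlock,
    chain_anchors,
    classify_tandem,
    coverage_percentage,
    filter_blocks,
    syntenic_depth,
)


def table(n, chrom="c1", genome="g", prefix="g"):
    return GeneTable.from_records(
        genome, [(f"{prefix}{i}", chrom, i * 1000, i * 1000 + 500, "+") for i in range(n)]
    )


def hit(q, s, e=1e-30):
    return HitRecord(q, s, e, 100.0)


class TestClassifyTandem:
    def test_adjacent_pair_in_array(self):
        genes = table(10)
        assert classify_tandem([hit("g7", "g8")], genes) == {"g7", "g8"}

    def test_cross_chromosome_pair_ignored(self):
        genes = GeneTable.from_records(
            "g", [("a", "c1", 0, 10, "+"), ("b", "c2", 0, 10, "+")]
        )
        assert classify_tandem([hit("a", "b")], genes) == set()

    def test_transitive_closure_merges_arrays(self):
        genes = table(10)
        got = classify_tandem([hit("g1", "g2"), hit("g2", "g3")], genes)
        assert got == {"g1", "g2", "g3"}

    def test_matches_bruteforce_closure_on_random_hits(self):
        rng = np.random.default_rng(5)
        genes = table(30)
        pairs = [
            (f"g{int(a)}", f"g{int(b)}")
            for a, b in rng.integers(0, 30, size=(40, 2))
            if a != b
        ]
        positions = {f"g{i}": ("c1", i) for i in range(30)}
        expected = oracle_tandem_arrays(pairs, positions, max_intervening=1)
        got = classify_tandem([hit(a, b) for a, b in pairs], genes, max_intervening=1)
        assert got == expected

    def test_unknown_gene_raises(self):
        with pytest.raises(KeyError):
            classify_tandem([hit("nope", "g1")], table(3))


class TestChainAnchors:
    def test_five_consecutive_anchors_form_minimal_block(self):
        ga, gb = table(10, genome="a", prefix="a"), table(10, genome="b", prefix="b")
        hits = [hit(f"a{i}", f"b{i}") for i in range(5)]
        blocks = chain_anchors(hits, ga, gb)
        assert len(blocks) == 1 and len(blocks[0]) == 5
        assert blocks[0].orientation == "same"

    def test_four_anchors_below_match_size_discarded(self):
        ga, gb = table(10, genome="a", prefix="a"), table(10, genome="b", prefix="b")
        assert chain_anchors([hit(f"a{i}", f"b{i}") for i in range(4)], ga, gb) == []

    def test_large_gap_splits_into_two_chains(self):
        # 10 anchors, a 30-gene gap (> max_gaps 25), then 10 more
        ga, gb = table(60, genome="a", prefix="a"), table(60, genome="b", prefix="b")
        idx = list(range(10)) + list(range(40, 50))
        hits = [hit(f"a{i}", f"b{i}") for i in idx]
        blocks = chain_anchors(hits, ga, gb)
        assert sorted(len(b) for b in blocks) == [10, 10]
        spans = sorted(b.span_a() for b in blocks)
        assert spans == [(0, 9), (40, 49)]

    def test_inverted_orientation_detected(self):
        ga, gb = table(10, genome="a", prefix="a"), table(10, genome="b", prefix="b")
        hits = [hit(f"a{i}", f"b{9 - i}") for i in range(6)]
        blocks = chain_anchors(hits, ga, gb)
        assert len(blocks) == 1 and blocks[0].orientation == "inverted"

    @pytest.mark.parametrize("seed", [7, 19, 23])
    def test_first_block_reaches_exhaustive_optimum(self, seed):
        """Greedy extraction starts from the best chain over both orientations."""
        rng = np.random.default_rng(seed)
        n = 14
        ga, gb = table(n, genome="a", prefix="a"), table(n, genome="b", prefix="b")
        pairs = {(int(a), int(b)) for a, b in rng.integers(0, n, size=(12, 2))}
        hits = [hit(f"a{i}", f"b{j}") for i, j in sorted(pairs)]
        params = ChainParams(match_size=2)
        blocks = chain_anchors(hits, ga, gb, params)
        fwd, _ = oracle_best_chain(sorted(pairs))
        inv, _ = oracle_best_chain(sorted((a, -b) for a, b in pairs))
        best = max(fwd, inv)
        assert blocks and max(b.score for b in blocks) == pytest.approx(best)

    def test_monotone_orders_in_every_block(self, small_sim):
        from paleofrac.synteny import ChainParams

        blocks = chain_anchors(
            small_sim.hits_dup_out1, small_sim.duplicated, small_sim.outgroup
        )
        assert blocks
        for b in blocks:
            oa = [p.order_a for p in b.pairs]
            ob = [p.order_b for p in b.pairs]
            assert oa == sorted(oa)
            sign = 1 if b.orientation == "same" else -1
            assert ob == sorted(ob, reverse=sign < 0)
            assert all(x < y for x, y in zip(oa, oa[1:]))

    def test_recovers_planted_blocks_at_full_retention(self):
        from paleofrac.synthetic_data import SimulationConfig, simulate_genomes

        cfg = SimulationConfig(
            seed=3,
            n_outgroup_genes=800,
            retention_probs=(1.0, 1.0),
            rearrangement_events=0,
            ancient_segments=0,
            tandem_arrays=0,
            spurious_hit_fraction=0.0,
        )
        sim = simulate_genomes(cfg)
        blocks = chain_anchors(sim.hits_dup_out1, sim.duplicated, sim.outgroup)
        # one block per (copy, chromosome), each spanning the whole chromosome
        assert len(blocks) == 2 * cfg.n_chromosomes
        sizes = sorted(len(b) for b in blocks)
        assert sizes == [100] * 16


class TestFilterBlocks:
    def _block(self, n_pairs, pair_e, block_e, bid=0):
        pairs = [
            AnchorPair(f"a{i}", f"b{i}", pair_e, "c1", i, "c2", i) for i in range(n_pairs)
        ]
        return SyntenicBlock(pairs, "c1", "c2", 50.0 * n_pairs, block_e, "same", block_id=bid)

    def test_high_block_evalue_removed(self):
        kept, log = filter_blocks([self._block(12, 1e-20, 1e-9)])
        assert kept == [] and list(log["reason"]) == ["block_evalue"]

    def test_small_block_with_weak_pairs_removed(self):
        # 8 pairs, 5 weak (62.5% > 50%)
        pairs = [
            AnchorPair(f"a{i}", f"b{i}", 1e-8 if i < 5 else 1e-30, "c1", i, "c2", i)
            for i in range(8)
        ]
        b = SyntenicBlock(pairs, "c1", "c2", 400.0, 1e-50, "same", block_id=1)
        kept, log = filter_blocks([b])
        assert kept == [] and list(log["reason"]) == ["weak_pairs"]

    def test_strong_block_kept(self):
        kept, log = filter_blocks([self._block(12, 1e-20, 1e-50)])
        assert len(kept) == 1 and len(log) == 0

    def test_output_subset_and_reasons_partition(self):
        blocks = [
            self._block(12, 1e-20, 1e-9, 0),
            self._block(12, 1e-20, 1e-50, 1),
            self._block(6, 1e-8, 1e-50, 2),
        ]
        kept, log = filter_blocks(blocks)
        assert {b.block_id for b in kept} | set(log["block_id"]) == {0, 1, 2}
        assert len(kept) + len(log) == 3


class TestSyntenicDepth:
    def _blocks(self):
        def mk(bid, chrom_a, lo, hi):
            pairs = [
                AnchorPair(f"x{bid}_{o}", f"b{o}", 1e-30, chrom_a, o, "c1", o)
                for o in range(lo, hi + 1)
            ]
            return SyntenicBlock(pairs, chrom_a, "c1", 100.0, 1e-50, "same", block_id=bid)

        return [mk(0, "a1", 0, 9), mk(1, "a2", 0, 4)]

    def test_depth_counts_distinct_covering_blocks(self):
        gt = table(12, chrom="c1", prefix="b")
        df = syntenic_depth(self._blocks(), "b", gt).set_index("ratio")
        assert df.loc["2:1", "gene_count"] == 5   # ranks 0-4 covered twice
        assert df.loc["1:1", "gene_count"] == 5   # ranks 5-9
        assert df.loc["0:1", "gene_count"] == 2   # ranks 10, 11

    def test_full_retention_simulator_is_all_depth_two(self):
        from paleofrac.synthetic_data import SimulationConfig, simulate_genomes

        cfg = SimulationConfig(
            seed=3,
            n_outgroup_genes=800,
            retention_probs=(1.0, 1.0),
            rearrangement_events=0,
            ancient_segments=0,
            tandem_arrays=0,
            spurious_hit_fraction=0.0,
        )
        sim = simulate_genomes(cfg)
        blocks = chain_anchors(sim.hits_dup_out1, sim.duplicated, sim.outgroup)
        df = syntenic_depth(blocks, "b", sim.outgroup).set_index("ratio")
        assert df.loc["2:1", "gene_count"] == 800
        assert df.loc["2:1", "pct_of_all_genes"] == 100.0


class TestCoveragePercentage:
    @pytest.mark.parametrize(
        "n_in,n_total,expected",
        [
            (11108, 26873, 41.34),
            (16509, 42341, 38.99),
            (9416, 32831, 28.68),
            (14132, 42341, 33.38),
            (12627, 26873, 46.99),
            (14915, 32831, 45.43),
            (0, 100, 0.00),
        ],
    )
    def test_printed_percentages(self, n_in, n_total, expected):
        assert coverage_percentage(n_in, n_total) == expected

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            coverage_percentage(0, 0)
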