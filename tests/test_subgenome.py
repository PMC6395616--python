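"""Region pairing, singleton counting and the subgenome-assignment rule."""

import numpy as np
import pytest

from paleofrac.io_formats import GeneTable
from paleofrac.subgenome import (
    RegionPair,
    assign_subgenomes,
    build_block_anchor_index,
    count_singletons,
    flag_high_confidence,
    pair_homologous_regions,
    region_order_key,
)
from paleofrac.synteny import AnchorPair, SyntenicBlock


def outgroup_table(n=20):
    return GeneTable.from_records(
        "out", [(f"o{i}", "c1", i * 1000, i * 1000 + 500, "+") for i in range(n)]
    )


def block(chrom_a, orders, prefix, score=500.0, bid=0):
    pairs = [
        AnchorPair(f"{prefix}{o}", f"o{o}", 1e-40, chrom_a, o, "c1", o) for o in orders
    ]
    return SyntenicBlock(pairs, chrom_a, "c1", score, 1e-100, "same", block_id=bid)


class TestRegionPairing:
    def test_two_blocks_over_same_interval_pair_up(self):
        b1 = block("d1", range(0, 10), "x", bid=0)
        b2 = block("d2", range(0, 10), "y", bid=1)
        pairs = pair_homologous_regions([b1, b2])
        assert len(pairs) == 1
        p = pairs[0]
        assert p.interval == (0, 10)
        assert {p.region_1, p.region_2} == {b1, b2}

    def test_single_cover_yields_absent_region2(self):
        pairs = pair_homologous_regions([block("d1", range(0, 8), "x")])
        assert len(pairs) == 1 and pairs[0].region_2 is None

    def test_nested_footprint_splits_segments(self):
        long = block("d1", range(0, 20), "x", score=900, bid=0)
        short = block("d2", range(5, 12), "y", score=300, bid=1)
        pairs = pair_homologous_regions([long, short])
        intervals = sorted(p.interval for p in pairs)
        assert intervals == [(0, 5), (5, 12), (12, 20)]
        mid = [p for p in pairs if p.interval == (5, 12)][0]
        assert mid.region_2 is short

    def test_three_covers_keep_top_two_by_score(self):
        b1 = block("d1", range(0, 10), "x", score=900, bid=0)
        b2 = block("d2", range(0, 10), "y", score=800, bid=1)
        b3 = block("d3", range(0, 10), "z", score=100, bid=2)
        pairs = pair_homologous_regions([b1, b2, b3])
        assert len(pairs) == 1
        assert {pairs[0].region_1, pairs[0].region_2} == {b1, b2}

    def test_simulator_pairing_matches_planted_structure(self, small_sim):
        """Without rearrangement noise every paired region is two planted
        segments covering the same outgroup interval."""
        from paleofrac.synteny import chain_anchors, filter_blocks

        blocks, _ = filter_blocks(
            chain_anchors(small_sim.hits_dup_out1, small_sim.duplicated, small_sim.outgroup)
        )
        pairs = pair_homologous_regions(blocks)
        assert pairs
        two_sided = [p for p in pairs if p.region_2 is not None]
        # paired regions must sit on different duplicated chromosomes or at
        # least be distinct blocks
        for p in two_sided:
            assert p.region_1 is not p.region_2


class TestCountSingletons:
    def _pair(self, ret1, ret2, n=10):
        """Build a RegionPair over n outgroup genes with given retention."""
        b1 = block("d1", [o for o in range(n) if ret1[o]], "x", bid=0)
        b2 = block("d2", [o for o in range(n) if ret2[o]], "y", bid=1)
        pair = RegionPair("c1", (0, n), b1, b2)
        return pair, build_block_anchor_index([b1, b2])

    def test_hand_enumerated_toy(self):
        ret1 = [1, 1, 0, 1, 0, 0, 1, 1, 0, 1]
        ret2 = [1, 0, 1, 1, 0, 0, 0, 1, 1, 1]
        pair, idx = self._pair(ret1, ret2)
        n1, n2 = count_singletons(pair, idx, outgroup_table(10))
        # by hand: only-1 at ranks 1, 6; only-2 at 2, 8; both at 0, 3, 7, 9; lost 4, 5
        assert (n1, n2) == (2, 2)
        assert pair.n_homeologs == 4
        assert pair.n_lost == 2
        assert n1 + n2 + pair.n_homeologs + pair.n_lost == 10

    def test_only_region1_increments_n1(self):
        pair, idx = self._pair([1, 0, 0, 0, 0, 0, 0, 0, 0, 0], [0] * 10)
        n1, n2 = count_singletons(pair, idx, outgroup_table(10))
        assert (n1, n2) == (1, 0)

    def test_both_regions_is_homeolog_not_singleton(self):
        pair, idx = self._pair([1] + [0] * 9, [1] + [0] * 9)
        n1, n2 = count_singletons(pair, idx, outgroup_table(10))
        assert (n1, n2) == (0, 0) and pair.n_homeologs == 1

    def test_tandem_genes_excluded(self):
        pair, idx = self._pair([1, 1] + [0] * 8, [0] * 10)
        n1, n2 = count_singletons(pair, idx, outgroup_table(10), dup_tandem={"x0"})
        assert (n1, n2) == (1, 0)


class TestAssignment:
    def _counted_pair(self, ret1, ret2, n=10):
        pair, idx = TestCountSingletons()._pair(ret1, ret2, n)
        count_singletons(pair, idx, outgroup_table(n))
        return pair

    def test_more_singletons_is_subgenome1(self):
        ret1 = [1] * 8 + [0, 0]   # 8 singletons in region 1
        ret2 = [0] * 8 + [1, 0]   # 1 in region 2
        pair = self._counted_pair(ret1, ret2)
        assignment = assign_subgenomes([pair], outgroup_table(10))
        assert pair.labels == ("subgenome1", "subgenome2")
        g = assignment.genes
        assert (g.loc[g.index.str.startswith("x"), "label"] == "subgenome1").all()

    def test_tie_broken_by_total_retained_then_chromosome(self):
        # equal singletons; region 1 has more homeologs -> more retained total
        assert region_order_key(4, 44, "d1") < region_order_key(4, 42, "d2")
        assert region_order_key(4, 40, "d1") < region_order_key(4, 40, "d2")

    def test_single_region_inherits_block_label(self):
        shared = block("d1", range(0, 10), "x", bid=0)
        other = block("d2", range(0, 10), "y", bid=1)
        lone_pair = RegionPair("c1", (10, 14), shared, None)
        both = RegionPair("c1", (0, 10), shared, other)
        idx = build_block_anchor_index([shared, other])
        gt = outgroup_table(14)
        count_singletons(both, idx, gt)
        count_singletons(lone_pair, idx, gt)
        assign_subgenomes([both, lone_pair], gt)
        assert lone_pair.labels[0] == both.labels[0]

    def test_partition_partner_symmetry_and_identity(self, small_result, small_sim):
        assignment = small_result.assignment
        g = assignment.genes
        assert set(g["label"].unique()) <= {"subgenome1", "subgenome2", "unassigned"}
        hom = g[g["gene_class"] == "homeolog"]
        # partner links are mutual and span both labels
        for gid, row in hom.sample(min(len(hom), 300), random_state=0).iterrows():
            assert g.loc[row["partner"], "partner"] == gid
            labs = {row["label"], g.loc[row["partner"], "label"]}
            assert labs == {"subgenome1", "subgenome2"}
        # per-pair counting identity (tandem-excluded outgroup genes)
        for pair in assignment.region_pairs:
            if pair.region_2 is None:
                continue
            total = pair.singleton_counts[0] + pair.singleton_counts[1]
            total += pair.n_homeologs + pair.n_lost
            assert total <= pair.n_outgroup_genes
        # subgenome-1 singletons >= subgenome-2 singletons per paired region
        for pair in assignment.region_pairs:
            if pair.region_2 is None or pair.labels is None:
                continue
            n1, n2 = pair.singleton_counts
            s1 = n1 if pair.labels[0] == "subgenome1" else n2
            s2 = n2 if pair.labels[0] == "subgenome1" else n1
            assert s1 >= s2

    def test_small_simulation_label_recovery(self, small_result, small_sim):
        from paleofrac.pipeline import label_accuracy

        acc = label_accuracy(small_result.assignment, small_sim.truth.genes)
        assert acc >= 0.95


class TestHighConfidence:
    def test_flag_requires_second_outgroup_anchor(self):
        b1 = block("d1", range(0, 10), "x", bid=0)
        b2 = block("d2", range(0, 10), "y", bid=1)
        pair = RegionPair("c1", (0, 10), b1, b2)
        idx = build_block_anchor_index([b1, b2])
        gt = outgroup_table(10)
        count_singletons(pair, idx, gt)
        assignment = assign_subgenomes([pair], gt)
        second = [block("d1", range(0, 5), "x", bid=9)]  # anchors x0..x4 only
        flag_high_confidence(assignment, second)
        g = assignment.genes
        assert bool(g.loc["x0", "high_confidence"])
        assert not bool(g.loc["x7", "high_confidence"])

    def test_full_retention_simulator_all_flagged(self):
        from paleofrac.pipeline import PipelineConfig, bundle_from_dataset, run_bundle
        from paleofrac.synthetic_data import SimulationConfig, simulate_genomes

        cfg = SimulationConfig(
            seed=5,
            n_outgroup_genes=800,
            retention_probs=(1.0, 1.0),
            rearrangement_events=0,
            ancient_segments=0,
            tandem_arrays=0,
            spurious_hit_fraction=0.0,
            second_outgroup_retention=1.0,
        )
        sim = simulate_genomes(cfg)
        from paleofrac.synthetic_data import SimulatedDataset

        ds = SimulatedDataset(**sim.__dict__)
        res = run_bundle(bundle_from_dataset(ds), PipelineConfig(seed=5))
        g = res.assignment.genes
        assert g["high_confidence"].all()
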