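"""Replicate pooling, weighted levels, metagene profiles, comparisons."""

import numpy as np
import pandas as pd
import pytest

from paleofrac.io_formats import FormatError, MethylationTable
from paleofrac.methylation import (
    MethylationIndex,
    compare_region_methylation,
    metagene_profile,
    pool_replicates,
    region_levels,
    weighted_methylation,
)


def meth_table(rows):
    return MethylationTable(
        pd.DataFrame(
            rows,
            columns=["chromosome", "position", "strand", "context", "count_methylated", "count_total"],
        )
    )


class TestPoolReplicates:
    def test_counts_sum_per_site(self):
        r1 = meth_table([("c1", 10, "+", "CG", 3, 10)])
        r2 = meth_table([("c1", 10, "+", "CG", 2, 10)])
        pooled = pool_replicates([r1, r2])
        row = pooled.df.iloc[0]
        assert (row["count_methylated"], row["count_total"]) == (5, 20)

    def test_site_in_one_replicate_carried_through(self):
        r1 = meth_table([("c1", 10, "+", "CG", 3, 10)])
        r2 = meth_table([("c1", 99, "-", "CHG", 1, 5)])
        pooled = pool_replicates([r1, r2])
        assert len(pooled) == 2

    def test_pooled_level_between_replicate_levels(self):
        r1 = meth_table([("c1", 10, "+", "CG", 9, 10)])   # 0.9
        r2 = meth_table([("c1", 10, "+", "CG", 1, 10)])   # 0.1
        pooled = pool_replicates([r1, r2]).df.iloc[0]
        level = pooled["count_methylated"] / pooled["count_total"]
        assert 0.1 <= level <= 0.9

    def test_conflicting_context_rejected(self):
        r1 = meth_table([("c1", 10, "+", "CG", 3, 10)])
        r2 = meth_table([("c1", 10, "+", "CHG", 2, 10)])
        with pytest.raises(FormatError, match="context"):
            pool_replicates([r1, r2])

    def test_invariant_to_splitting_a_replicate(self):
        rng = np.random.default_rng(0)
        rows = [
            ("c1", int(p), "+", "CG", int(m), int(m + u))
            for p, m, u in zip(
                rng.choice(10_000, 200, replace=False),
                rng.integers(0, 5, 200),
                rng.integers(1, 5, 200),
            )
        ]
        whole = meth_table(rows)
        part1, part2 = meth_table(rows[:120]), meth_table(rows[120:])
        a = pool_replicates([whole]).df.reset_index(drop=True)
        b = pool_replicates([part1, part2]).df.reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestWeightedMethylation:
    def test_pooled_ratio_not_mean_of_ratios(self):
        t = meth_table(
            [("c1", 11, "+", "CG", 3, 10), ("c1", 21, "+", "CG", 1, 10)]
        )
        r = weighted_methylation(t, "g", "c1", 0, 100, "CG")
        assert r.level == pytest.approx(4 / 20)
        assert r.covered_cytosines == 2

    def test_uncovered_region_is_absent(self):
        t = meth_table([("c1", 500, "+", "CG", 3, 10)])
        assert weighted_methylation(t, "g", "c1", 0, 100, "CG") is None

    def test_fully_methylated(self):
        t = meth_table([("c1", 11, "+", "CG", 10, 10)])
        assert weighted_methylation(t, "g", "c1", 0, 100, "CG").level == 1.0

    def test_min_total_filters_low_coverage(self):
        t = meth_table(
            [("c1", 11, "+", "CG", 1, 2), ("c1", 21, "+", "CG", 5, 10)]
        )
        r = weighted_methylation(t, "g", "c1", 0, 100, "CG", min_total=4)
        assert r.covered_cytosines == 1
        assert r.level == pytest.approx(0.5)


def uniform_table(chrom, lo, hi, spacing, level, context="CG", depth=10):
    positions = np.arange(lo, hi, spacing)
    m = int(round(level * depth))
    return meth_table(
        [(chrom, int(p) + 1, "+", context, m, depth) for p in positions]
    )


class TestMetageneProfile:
    def genes(self, strand="+"):
        return pd.DataFrame(
            {
                "gene_id": ["g1"],
                "chromosome": ["c1"],
                "start": [5000],
                "end": [7000],
                "strand": [strand],
            }
        )

    def test_uniform_methylation_flat_profile(self):
        t = uniform_table("c1", 0, 12_000, 20, 0.5)
        prof = metagene_profile(self.genes(), t, "CG")
        assert np.allclose(prof.levels, 0.5)
        assert prof.n_genes == 1
        assert len(prof.levels) == 30 + 40 + 30

    def test_minus_strand_flips_to_transcription_axis(self):
        # methylation only genomically 3' of the span: for a minus-strand
        # gene that region is its (5') upstream flank
        t = uniform_table("c1", 7000, 10_000, 20, 0.8)
        prof = metagene_profile(self.genes("-"), t, "CG")
        assert np.nanmean(prof.upstream) == pytest.approx(0.8)
        assert np.all(np.isnan(prof.downstream))

    def test_body_elevation_visible_in_body_bins(self):
        rows = pd.concat(
            [
                uniform_table("c1", 2000, 5000, 20, 0.2).df,
                uniform_table("c1", 5000, 7000, 20, 0.7).df,
                uniform_table("c1", 7000, 10_000, 20, 0.2).df,
            ]
        ).reset_index(drop=True)
        prof = metagene_profile(self.genes(), MethylationTable(rows), "CG")
        assert np.nanmean(prof.body) > np.nanmean(prof.upstream) + 0.4

    def test_short_gene_contributes_proportionally(self):
        genes = self.genes().assign(start=5000, end=5020)  # 20 bp, 40 body bins
        t = uniform_table("c1", 0, 12_000, 7, 0.5)
        prof = metagene_profile(genes, t, "CG")
        assert np.nanmax(np.abs(prof.levels[np.isfinite(prof.levels)] - 0.5)) < 1e-9


class TestCompareRegionMethylation:
    def _genes(self, n, chrom="c1", start0=10_000, spacing=10_000, prefix="g"):
        return pd.DataFrame(
            {
                "gene_id": [f"{prefix}{i}" for i in range(n)],
                "chromosome": chrom,
                "start": [start0 + i * spacing for i in range(n)],
                "end": [start0 + i * spacing + 2000 for i in range(n)],
                "strand": "+",
            }
        )

    def test_identical_groups_p_one(self):
        genes = self._genes(5)
        t = uniform_table("c1", 0, 70_000, 50, 0.4)
        res = compare_region_methylation(genes, genes, "body", "CG", t)
        assert res.p_value == 1.0

    def test_too_few_covered_genes_rejected(self):
        genes = self._genes(2)
        t = uniform_table("c1", 0, 40_000, 50, 0.4)
        with pytest.raises(ValueError):
            compare_region_methylation(genes, genes, "body", "CG", t)

    def test_planted_chg_body_difference_detected(self):
        """+0.15 CHG body difference at n = 500 vs 500 gives p < 0.01."""
        from paleofrac.synthetic_data import SimulationConfig, simulate_genomes, simulate_methylation

        cfg = SimulationConfig(seed=31, n_outgroup_genes=1500)
        cfg.methylation.max_genes = 1000
        sim = simulate_genomes(cfg)
        chosen = sim.truth.genes.index[:1000]
        # logit shift that lifts the CHG body mean level by ~0.15
        group_a = list(chosen[:500])
        group_b = list(chosen[500:1000])
        shift = pd.DataFrame({"CHG_body": 1.1}, index=group_b)
        reps, _ = simulate_methylation(
            sim.duplicated, sim.truth, cfg, extra_logit=shift, gene_subset=list(chosen)
        )
        pooled = pool_replicates(reps)
        index = MethylationIndex(pooled)
        gdf = sim.duplicated.df
        ga = gdf[gdf["gene_id"].isin(group_a)]
        gb = gdf[gdf["gene_id"].isin(group_b)]
        res = compare_region_methylation(ga, gb, "body", "CHG", index)
        assert res.p_value < 0.01
        assert res.median_b > res.median_a

    def test_levels_match_generative_means(self):
        """Weighted levels on simulator output sit at the configured means."""
        from paleofrac.synthetic_data import SimulationConfig, simulate_genomes, simulate_methylation

        cfg = SimulationConfig(seed=13, n_outgroup_genes=1200)
        cfg.methylation.max_genes = 400
        cfg.methylation.gene_sd_logit = 0.0
        sim = simulate_genomes(cfg)
        reps, truth_levels = simulate_methylation(sim.duplicated, sim.truth, cfg)
        index = MethylationIndex(pool_replicates(reps))
        gdf = sim.duplicated.df
        genes = gdf[gdf["gene_id"].isin(truth_levels.index)]
        for ctx, region, mean in (("CG", "body", 0.55), ("CHG", "body", 0.10)):
            lv = region_levels(genes, index, ctx, region).dropna()
            assert abs(lv.mean() - mean) < 0.02
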