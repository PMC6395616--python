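"""Shared fixtures: simulated datasets at unit-test and study scale."""

from __future__ import annotations

import pytest

from paleofrac.pipeline import (
    PipelineConfig,
    bundle_from_dataset,
    config_from_paths,
    run_all,
    run_bundle,
)
from paleofrac.synthetic_data import (
    SimulatedDataset,
    SimulationConfig,
    biased_preset,
    simulate_cds,
    simulate_dataset,
    simulate_genomes,
    unbiased_preset,
    write_dataset,
)


def small_config(seed: int = 11, **kw) -> SimulationConfig:
    cfg = SimulationConfig(seed=seed, n_outgroup_genes=1600, **kw)
    cfg.expression.n_intergenic = 1000
    cfg.methylation.max_genes = 600
    return cfg


@pytest.fixture(scope="session")
def small_sim():
    """Genome trio only (no sequence/expression layers), 1,600 outgroup genes."""
    return simulate_genomes(small_config())


@pytest.fixture(scope="session")
def small_ds():
    """Full small dataset including CDS, expression and methylation."""
    return simulate_dataset(small_config())


@pytest.fixture(scope="session")
def small_result(small_ds):
    """Pipeline result on the small dataset (in memory)."""
    return run_bundle(bundle_from_dataset(small_ds), PipelineConfig(seed=11))


@pytest.fixture(scope="session")
def unbiased_run(tmp_path_factory):
    """Study-scale unbiased run (8,000 outgroup genes, seed 1), through files.

    The dataset is written to disk and read back by the pipeline so the run
    exercises every reader; returns (dataset, pipeline result).
    """
    ds = simulate_dataset(unbiased_preset(1))
    outdir = tmp_path_factory.mktemp("unbiased")
    paths = write_dataset(ds, str(outdir / "inputs"))
    config = config_from_paths(paths, seed=1, outdir=str(outdir / "products"))
    return ds, run_all(config)


@pytest.fixture(scope="session")
def biased_run():
    """Study-scale biased run (p1 - p2 = 0.15, seed 1); genomes + CDS only."""
    sim = simulate_genomes(biased_preset(1))
    ds = SimulatedDataset(**sim.__dict__, cds=simulate_cds(sim))
    return ds, run_bundle(bundle_from_dataset(ds), PipelineConfig(seed=1))
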