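"""Shared fixtures: toy genomes and session-scoped simulation runs.

The heavier acceptance-style properties (family sizes, multi-outgroup
power, no-noise recovery) share one batch of default-condition
simulations so each is generated and scored exactly once per session.
"""

from __future__ import annotations

import pytest

from ohnoscan import (
    DESK_SCALE_W_SET,
    Dataset,
    Genome,
    PipelineConfig,
    SIMULATOR_NODE_POLICY,
    SimConfig,
    run_pipeline,
    simulate,
)

#: seeds of the shared default-condition simulation batch
BATCH_SEEDS = tuple(range(1, 11))

SIM_PIPELINE_CONFIG = PipelineConfig(
    W_set=DESK_SCALE_W_SET, node_policy=SIMULATOR_NODE_POLICY
)


@pytest.fixture
def linear_genome() -> Genome:
    """One 36-gene chromosome: 31 possible placements of a 5-gene window."""
    return Genome.from_chromosomes("toy", {"chr1": [f"v{i}" for i in range(1, 37)]})


@pytest.fixture
def two_chrom_genome() -> Genome:
    return Genome.from_chromosomes(
        "toy2",
        {
            "chrA": [f"a{i}" for i in range(1, 21)],
            "chrB": [f"b{i}" for i in range(1, 16)],
        },
    )


@pytest.fixture(scope="session")
def sim_batch():
    """Default-condition simulations with their full pipeline runs."""
    batch = []
    for seed in BATCH_SEEDS:
        sim = simulate(SimConfig(seed=seed))
        result = run_pipeline(Dataset.from_simulation(sim), SIM_PIPELINE_CONFIG)
        batch.append((sim, result))
    return batch


@pytest.fixture(scope="session")
def no_noise_run():
    """Pure-2R limit: full retention, no rearrangement, loss or SSDs."""
    sim = simulate(
        SimConfig(
            n_genes=200,
            n_chromosomes=2,
            retention=1.0,
            inversion_rate=0.0,
            translocation_rate=0.0,
            outgroup_inversion_rate=0.0,
            outgroup_translocation_rate=0.0,
            loss_rate_outgroup=0.0,
            ssd_rate=0.0,
            ancient_paralog_rate=0.0,
            n_vertebrates=2,
            seed=7,
        )
    )
    cfg = PipelineConfig(W_set=(10, 20, 30), node_policy=SIMULATOR_NODE_POLICY)
    return sim, run_pipeline(Dataset.from_simulation(sim), cfg)
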