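"""Shared fixtures: one small simulated dataset reused across module tests.

The small genome (3 chromosomes x 400 kb, 40 genes incl. a planted 12-gene
ovary cluster, 3 off-assembly genes) keeps alignment-backed tests fast;
acceptance-level runs at full scale live in test_acceptance.py.
"""

import numpy as np
import pytest

from kaikobuild.pipeline import run_pipeline
from kaikobuild.simulate import (
    ClusterSpec, SimulationConfig, simulate_genome, simulate_libraries,
)


def small_config(**overrides) -> SimulationConfig:
    base = dict(
        seed=11,
        n_chromosomes=3,
        chromosome_length=400_000,
        n_genes=40,
        n_unplaced_genes=3,
        cluster_plant_spec=[ClusterSpec("ovary", "chr2", 100_000, 12, n_duplicated=5)],
        n_mrna=4,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    cfg = small_config()
    genome, truth = simulate_genome(cfg)
    records = simulate_libraries(genome, truth, cfg)
    return cfg, genome, truth, records


@pytest.fixture(scope="session")
def small_result():
    """Full pipeline on the small genome (default error rates)."""
    return run_pipeline(small_config())


@pytest.fixture()
def rng():
    # function-scoped so each test sees the same stream regardless of
    # execution order
    return np.random.default_rng(7)
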