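"""Shared fixtures: a default synthetic ecosystem, reused across the suite.

The default simulation (~2,000 cells, 6,000 genes, one planted 300-gene 1.5x
amplification) is expensive enough that it is built once per session; tests
treat it as read-only.
"""

import numpy as np
import pytest

import ecosys


@pytest.fixture(scope="session")
def ecosystem():
    """(CountMatrix, GroundTruth) under the default study conditions."""
    return ecosys.simulate_ecosystem(ecosys.SimConfig(seed=0))


@pytest.fixture(scope="session")
def counts(ecosystem):
    return ecosystem[0]


@pytest.fixture(scope="session")
def truth(ecosystem):
    return ecosystem[1]


@pytest.fixture(scope="session")
def norm(counts):
    return ecosys.normalize_log(counts)


@pytest.fixture(scope="session")
def scaled(norm):
    return ecosys.scale_expression(norm)


@pytest.fixture(scope="session")
def malignancy(norm, truth):
    """End-to-end malignancy call on the default ecosystem (used by several tests)."""
    return ecosys.call_malignancy_pipeline(
        norm, truth.gene_positions, truth.cell_type, seed=0
    )


@pytest.fixture(scope="session")
def small_config():
    """A light configuration for tests that re-simulate repeatedly."""
    return ecosys.SimConfig(
        n_genes=2000,
        n_cells_per_sample=120,
        samples=(("CC1", "CC"), ("GBC1", "PT"), ("GBC2", "PT"), ("MT1", "MT")),
        cnv_blocks=(("chr1", 20, 150, 1.5),),
        seed=7,
    )


def rng(seed=0):
    return np.random.default_rng(seed)
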