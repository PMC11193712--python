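"""Shared fixtures: scaled-down synthetic datasets for fast unit tests."""

import dataclasses

import numpy as np
import pytest

from cpatac import simulate as sim
from cpatac.core import InsertionTrack


@pytest.fixture(scope="session")
def small_params() -> sim.SimParams:
    """A 20-kb genome with the default statistical structure."""
    return dataclasses.replace(
        sim.SimParams(),
        genome_length=20_000, lsc_length=12_000, ira_length=3_000, ssc_length=2_000,
        n_genes=12, cds_length_range=(300, 900), rrna_length_range=(900, 1200),
        n_footprints=40, depth=200_000,
    )


@pytest.fixture(scope="session")
def small_genome(small_params):
    return sim.simulate_genome(small_params, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_params, small_genome):
    genome, annotation = small_genome
    return sim.simulate_truth(genome, annotation, small_params, seed=12)


@pytest.fixture(scope="session")
def small_track(small_truth):
    return sim.simulate_atac(small_truth, seed=13)


@pytest.fixture()
def uniform_track():
    """Constant-rate track on a 2-kb toy genome."""
    return InsertionTrack(genome_name="toy", counts=np.full(2000, 5.0), label="uniform")
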