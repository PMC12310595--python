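from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from m3c import (
    LocusModel,
    NLAIII,
    build_sequence_index,
    digest_genome,
    simulate_genome,
)

TOY_SEQUENCE = "AACATGGGCATGTT"  # CATG at 2 and 8 -> fragments [0,6) [6,12) [12,14)


@pytest.fixture(scope="session")
def toy_genome():
    return {"chr1": TOY_SEQUENCE}


@pytest.fixture(scope="session")
def toy_map(toy_genome):
    return digest_genome(toy_genome, NLAIII)


@pytest.fixture(scope="session")
def toy_index(toy_genome, toy_map):
    return build_sequence_index(toy_map, toy_genome)


@pytest.fixture(scope="session")
def small_model():
    """A compact locus for integration tests (fast to simulate)."""
    return LocusModel(genome_length=60_000, viewpoint_pos=30_000)


@pytest.fixture(scope="session")
def small_locus(small_model):
    genome, fmap = simulate_genome(small_model, 1234)
    index = build_sequence_index(fmap, genome)
    return genome, fmap, index


def random_genome(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
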