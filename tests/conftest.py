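import numpy as np
import pytest

from lintrace.core import MISSING, CharacterMatrix
from lintrace.sim import SimulationParams, simulate_lineage


@pytest.fixture
def small_matrix() -> CharacterMatrix:
    """4 cells x 3 characters, no missing data."""
    return CharacterMatrix(
        [[1, 2, 0],
         [1, 3, 0],
         [0, 2, 1],
         [0, 0, 1]],
        ["a", "b", "c", "d"])


@pytest.fixture
def missing_matrix() -> CharacterMatrix:
    return CharacterMatrix(
        [[1, MISSING],
         [0, 2]],
        ["a", "b"])


@pytest.fixture(scope="session")
def perfect_experiment():
    """Perfect-phylogeny simulation: unique states, no dropout, sparse
    sampling so sampled cells are essentially always distinct."""
    params = SimulationParams(
        num_characters=20, num_states=10, depth=10, mutation_rate=0.1,
        dropout_rates=0.0, subsample=32 / 1024, unique_states=True, seed=7)
    return simulate_lineage(params)


@pytest.fixture(scope="session")
def default_experiment():
    """One replicate of the default benchmarking regime (scaled down to 128
    cells for unit-test speed)."""
    params = SimulationParams(
        num_characters=40, num_states=40, depth=9, mutation_rate=0.025,
        dropout_rates=0.17, subsample=128 / 512, seed=3)
    return simulate_lineage(params)
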