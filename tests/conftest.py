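import numpy as np
import pytest

from mosc.synth import (generate_single_cell_dataset, make_genome)
from mosc.tiling import tile_by_informative_cpgs


@pytest.fixture(scope="session")
def genome():
    return make_genome(seed=1)


@pytest.fixture(scope="session")
def small_genome():
    """Reduced genome for fast tests: fewer blocks per density."""
    return make_genome(blocks_per_density=4, seed=2)


@pytest.fixture(scope="session")
def sc_dataset(small_genome):
    """Steady-state single-cell dataset, 40 cells."""
    return generate_single_cell_dataset(small_genome, n_cells=40, seed=3)


@pytest.fixture(scope="session")
def sc_tiles(sc_dataset):
    return tile_by_informative_cpgs(sc_dataset.calls, window=50)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
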