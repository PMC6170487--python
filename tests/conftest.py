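import numpy as np
import pytest

from deforisk.grids import GridSpec
from deforisk.synthetic import SyntheticConfig, generate_landscape, generate_species


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_rows=120,
        n_cols=120,
        cell_size=1000.0,
        n_islands=3,
        n_species=25,
        seed=42,
    )


@pytest.fixture(scope="session")
def landscape(small_config):
    return generate_landscape(small_config)


@pytest.fixture(scope="session")
def species(small_config, landscape):
    return generate_species(small_config, landscape)


@pytest.fixture
def flat_grid() -> GridSpec:
    return GridSpec(n_rows=20, n_cols=20, cell_size=150.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
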