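import numpy as np
import pytest

from hexdiv.geogrid import Grid, GridSpec, build_grid
from hexdiv.synthetic import WorldConfig, generate_world


@pytest.fixture(scope="session")
def coarse_grid() -> Grid:
    """Coarse global grid (~1800 km median cells) shared across tests."""
    return build_grid(GridSpec(1800.0))


@pytest.fixture(scope="session")
def main_grid() -> Grid:
    """The study's main resolution (500 km median cells)."""
    return build_grid(GridSpec(500.0))


@pytest.fixture(scope="session")
def small_world(coarse_grid):
    """A small but complete synthetic world on the coarse grid."""
    cfg = WorldConfig(n_languages=200, n_features_binary=4,
                      categorical_state_counts=(3,), n_populations=30,
                      individuals_per_population=8, n_snps=500, seed=3)
    return generate_world(cfg, coarse_grid)
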