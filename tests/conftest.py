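import numpy as np
import pytest

from chromalight.spectra import SpectralDistribution, WavelengthGrid
from chromalight.standards import equal_energy_white, tables_for_grid
from chromalight.synthetic import SyntheticConfig


@pytest.fixture(scope="session")
def surface_grid():
    return WavelengthGrid.surface()


@pytest.fixture(scope="session")
def daylight_grid():
    return WavelengthGrid.daylight()


@pytest.fixture(scope="session")
def tables5(surface_grid):
    return tables_for_grid(surface_grid)


@pytest.fixture(scope="session")
def tables1(daylight_grid):
    return tables_for_grid(daylight_grid)


@pytest.fixture(scope="session")
def eew5(surface_grid):
    return equal_energy_white(surface_grid)


@pytest.fixture(scope="session")
def cfg():
    """Synthetic-study configuration with a fixed test seed."""
    return SyntheticConfig(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_spd(grid: WavelengthGrid, rng, kind="relative") -> SpectralDistribution:
    return SpectralDistribution(grid, rng.random(grid.n_channels), kind)
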