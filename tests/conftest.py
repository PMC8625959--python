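import numpy as np
import pytest

from mtvm.matrix_doubling import AngularGrid
from mtvm.presets import canopy_species
from mtvm.scatterer_models import species_kernels


@pytest.fixture(scope="session")
def grid():
    """Default angular grid with the 43 deg incidence node."""
    return AngularGrid.build(n_zenith=8, n_azimuth=16, theta_inc_deg=43.0)


@pytest.fixture(scope="session")
def kernels_a(grid):
    """Canopy A species kernels at C band (leaf disc + stalk)."""
    return [species_kernels(s, 5.3, grid) for s in canopy_species("A", 5.3)]


@pytest.fixture(scope="session")
def kernels_b(grid):
    """Canopy B species kernels at C band (needle leaf + branch)."""
    return [species_kernels(s, 5.3, grid) for s in canopy_species("B", 5.3)]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
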