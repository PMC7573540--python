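import numpy as np
import pytest

import visuomap as vm
from visuomap.synth import DEFAULT_AREA_PROFILES, sample_vertex_population


@pytest.fixture(scope="session")
def mapping_apertures():
    """One 90 s block of the wedge-and-ring mapping aperture."""
    return vm.wedge_ring_apertures()


@pytest.fixture(scope="session")
def bp_grid():
    return vm.default_backprojection_grid()


@pytest.fixture(scope="session")
def v1_population():
    """A mid-sized V1-like pRF population within the mapped field."""
    tab = sample_vertex_population(DEFAULT_AREA_PROFILES["V1"], 2000, seed=42)
    return tab[np.hypot(tab.x, tab.y) < 8.4].reset_index(drop=True)


@pytest.fixture(scope="session")
def diamond_masks(bp_grid):
    return vm.diamond_region_masks(bp_grid)
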