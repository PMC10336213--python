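import numpy as np
import pytest

import mosaicspect.geometry as geo
from mosaicspect.phantoms import make_uniform_cylinder
from mosaicspect.transport import build_slice_system, simulate


@pytest.fixture(scope="session")
def full_geometry():
    return geo.build_system()


@pytest.fixture(scope="session")
def grid2mm():
    return geo.default_grid_2mm()


@pytest.fixture(scope="session")
def uniform_run_200k(full_geometry, grid2mm):
    """Uniform-cylinder list-mode run on the full 3-D system (window on)."""
    activity = make_uniform_cylinder(grid2mm)
    return simulate(activity, full_geometry, 200_000, seed=20230628)


@pytest.fixture(scope="session")
def slice_system():
    return build_slice_system()


@pytest.fixture(scope="session")
def prototype_matrix():
    """13-position virtual-ring matrix from a 20k-photon-per-position run."""
    from mosaicspect.validation import build_prototype_matrix

    return build_prototype_matrix(seed=7, n_per_position=20_000)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
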