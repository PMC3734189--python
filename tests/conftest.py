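import numpy as np
import pytest

from aqvt import generate_quadratic_tissue


@pytest.fixture(scope="session")
def small_phantom():
    """12 anisotropic cells in a 9x9x9 µm box at 0.3 µm voxels."""
    return generate_quadratic_tissue(
        seed=11, n_cells=12, domain=(9.0, 9.0, 9.0), voxel_size=(0.3, 0.3, 0.3)
    )


@pytest.fixture(scope="session")
def small_iso_phantom():
    """Isotropic (identity-metric) phantom: its own Euclidean Voronoi diagram."""
    return generate_quadratic_tissue(
        seed=3, n_cells=12, domain=(9.0, 9.0, 9.0), voxel_size=(0.3, 0.3, 0.3),
        anisotropy_range=(1.0, 1.0),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
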