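import numpy as np
import pytest

import dmsapk as d


@pytest.fixture(scope="session")
def small_phantom():
    """32-cube phantom (0.875 cm voxels): fast enough for reconstruction
    tests, coarse enough to keep the suite quick."""
    return d.make_phantom(grid_shape=(32, 32, 32), voxel_size_cm=0.875)


@pytest.fixture(scope="session")
def small_geometry():
    return d.AcquisitionGeometry(n_views=24, orbit_radius_cm=15.0)


@pytest.fixture(scope="session")
def sensitivity():
    return d.SensitivityFactor(cpm_per_mbq=5000.0)


@pytest.fixture(scope="session")
def response():
    return d.CollimatorResponse()
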