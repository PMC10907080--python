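import numpy as np
import pytest

from desnet.grid import MaskVolume, VolumeGrid


@pytest.fixture
def identity_grid():
    """10^3 grid with 1 mm voxels and identity affine."""
    return VolumeGrid((10, 10, 10), np.eye(4))


@pytest.fixture
def mm2_grid():
    """9^3 grid with 2 mm isotropic voxels, origin at voxel 0."""
    return VolumeGrid((9, 9, 9), np.diag([2.0, 2.0, 2.0, 1.0]))


@pytest.fixture
def full_mask(identity_grid):
    return MaskVolume(identity_grid, np.ones(identity_grid.dims))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
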