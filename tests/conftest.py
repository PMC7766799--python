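import numpy as np
import pytest

from leadtract.grids_io import VolumeGrid


@pytest.fixture
def iso2mm_grid():
    """8x8x8 empty grid, 2 mm isotropic, origin at world 0."""
    return VolumeGrid(data=np.zeros((8, 8, 8)), affine=np.diag([2.0, 2.0, 2.0, 1.0]))


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def centered_grid(shape, voxel_mm):
    """Isotropic grid whose world origin is at the volume centre."""
    shape = tuple(shape)
    affine = np.diag([voxel_mm] * 3 + [1.0])
    affine[:3, 3] = [-(n - 1) * voxel_mm / 2.0 for n in shape]
    return VolumeGrid(data=np.zeros(shape), affine=affine)
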