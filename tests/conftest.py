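import numpy as np
import pytest

from gbmpar import BinaryMask, VolumeImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_grid():
    """Small isotropic grid helpers for mask/map construction."""
    shape = (12, 10, 8)

    def make_mask(vox=None):
        if vox is None:
            vox = np.zeros(shape, dtype=bool)
        return BinaryMask(voxels=vox, spacing=(1.0, 1.0, 1.0))

    def make_map(vox=None, units="a.u."):
        if vox is None:
            vox = np.zeros(shape)
        return VolumeImage(voxels=vox, spacing=(1.0, 1.0, 1.0), units=units)

    return shape, make_mask, make_map


def random_mask_pair(rng, shape=(8, 8, 6), p=0.3):
    a = BinaryMask(rng.random(shape) < p, spacing=(1, 1, 1))
    b = BinaryMask(rng.random(shape) < p, spacing=(1, 1, 1))
    return a, b
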