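import numpy as np
import pytest

from petnoise import PatientMeta, PhantomSpec, SuvVolume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """Small phantom spec used across tests to keep runtimes low."""
    return PhantomSpec(grid_size=(64, 64, 24), sigma_ref=0.15, seed=7)


def make_homogeneous_volume(shape_zyx, mean=1.0, sigma=0.0, spacing=(3.0, 3.0, 3.0), seed=0):
    """Body-everywhere volume with optional Gaussian noise (the mask covers all)."""
    rng = np.random.default_rng(seed)
    vox = np.full(shape_zyx, float(mean))
    if sigma > 0:
        vox = vox + rng.standard_normal(shape_zyx) * sigma
    return SuvVolume(voxels=vox, spacing=spacing, meta=PatientMeta())


@pytest.fixture
def homogeneous_volume_factory():
    return make_homogeneous_volume
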