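import numpy as np
import pytest

import voxelrep as vr


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_phantom():
    """The default 64^3 four-texture phantom (seed 1)."""
    spec = vr.default_phantom_spec(seed=1)
    return vr.generate_phantom(spec)


@pytest.fixture(scope="session")
def small_volume():
    """A quick 32^3 noise-free two-region phantom for cheap tests."""
    spec = vr.PhantomSpec(
        shape=(32, 32, 32),
        regions=[
            vr.RegionSpec("background", vr.TextureSpec(
                "smooth", intensity_mean=0.7, intensity_contrast=0.0,
                noise_sd=0.0), label=0, name="bg"),
            vr.RegionSpec("ellipsoid", vr.TextureSpec(
                "speckle", intensity_mean=0.4, intensity_contrast=0.2,
                noise_sd=0.0), label=1, name="blob",
                center=(16, 16, 16), radii=(8, 7, 6)),
        ],
        seed=3,
    )
    return vr.generate_phantom(spec)
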