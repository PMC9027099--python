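import numpy as np
import pytest

from thinsr.model import GeneratorConfig, build_generator
from thinsr.volume_io import Volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume(rng):
    """Standardized-range 12x12x12 random volume with anisotropic spacing."""
    vox = rng.uniform(0, 10000, size=(12, 12, 12)).astype(np.float32)
    return Volume(vox, spacing=(1.0, 1.0, 4.0), intensity_range=(0.0, 10000.0))


@pytest.fixture
def tiny_generator():
    """Small untrained generator usable on any patch size."""
    return build_generator(
        GeneratorConfig(n_residual_layers=2, channels=4), seed=0
    )


def profile_volume(profile, nx=4, ny=4, dz=1.0):
    """Volume whose every (x, y) column carries the given z profile."""
    profile = np.asarray(profile, dtype=np.float32)
    vox = np.broadcast_to(profile, (nx, ny, profile.size)).copy()
    return Volume(vox, spacing=(1.0, 1.0, dz))
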