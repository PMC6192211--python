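import numpy as np
import pytest

from smlm_fidelity import (
    DensityImage,
    make_filament_phantom,
    make_nucleus_phantom,
)


@pytest.fixture(scope="session")
def filament_small():
    """256x256 filament phantom shared by fast tests."""
    return make_filament_phantom(256, 256, 6.4, n_filaments=4, thickness=50.0, seed=3)


@pytest.fixture(scope="session")
def nucleus_small():
    """256x256 nucleus phantom shared by fast tests."""
    return make_nucleus_phantom(256, 256, 6.4, n_blobs=3, blob_radius=280.0, seed=3)


@pytest.fixture(scope="session")
def uniform_density():
    """Uniform density map: every candidate is accepted."""
    return DensityImage(np.ones((256, 256)), 6.4)


def random_image(seed: int, shape=(64, 64)) -> np.ndarray:
    return np.random.default_rng(seed).random(shape)
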