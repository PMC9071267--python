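import numpy as np
import pytest

from dreamgan.datasets import generate_synthetic
from dreamgan.networks import init_parameters

TINY_TRUNK = (4, 6, 8)
TINY_LATENT = 8


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_params():
    """Small but fully functional network (function-scoped: tests may train it)."""
    return init_parameters(latent_dim=TINY_LATENT, seed=0,
                           trunk_channels=TINY_TRUNK, init_std=0.15)


@pytest.fixture
def image_batch(rng):
    return rng.uniform(-1.0, 1.0, size=(6, 3, 32, 32))


@pytest.fixture(scope="session")
def small_dataset():
    return generate_synthetic(num_classes=3, n_per_class=40, seed=5,
                              split="train")
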