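import numpy as np
import pytest

from modclass.config import ExperimentConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def rgb_image(rng):
    return rng.integers(0, 256, (32, 32, 3))


@pytest.fixture
def gray_image(rng):
    return rng.integers(0, 256, (32, 32))


@pytest.fixture
def small_config():
    """Desk-scale configuration matched to 64x64 synthetic images."""
    return ExperimentConfig(
        standardize_size=64,
        codebook_size=20,
        seed=0,
        confusion_groups=(("NM", "PET"),),
    )
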