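import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from neolus.pipeline import phantom_feature_table


@pytest.fixture(scope="session")
def small_cohort_table():
    """2 subjects/class x 3 videos x 2 frames = 72 images, featurized once."""
    return phantom_feature_table(2, 3, 2, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def speckle_fixture(seed: int, shape=(128, 128)) -> np.ndarray:
    """Blurred Rayleigh speckle raster, the canonical random texture."""
    raw = np.random.default_rng(seed).rayleigh(1.0, shape)
    return gaussian_filter(raw, 1.2)
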