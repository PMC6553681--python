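import numpy as np
import pandas as pd
import pytest

from texrad.features.config import TextureConfig
from texrad.pipeline import FeatureTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cfg():
    return TextureConfig()


@pytest.fixture
def full_mask():
    def _make(shape):
        return np.ones(shape, dtype=bool)
    return _make


def make_feature_table(x: np.ndarray, labels: np.ndarray,
                       prefix: str = "SIM:ROI") -> FeatureTable:
    """Wrap a raw matrix as a cleaned-shape FeatureTable for model tests."""
    n, m = x.shape
    ids = [f"S{i:03d}" for i in range(n)]
    cols = [f"{prefix}:F{j:03d}" for j in range(m)]
    data = pd.DataFrame(x, index=ids, columns=cols)
    lab = pd.Series(np.asarray(labels, dtype=int), index=ids, name="label")
    return FeatureTable(data=data, labels=lab)


@pytest.fixture
def feature_table_factory():
    return make_feature_table


def random_masked_slice(rng, shape=(8, 8), n_grey=4, mask_p=0.8):
    """A random quantized slice with a random (non-empty) mask."""
    from texrad.features.quantize import quantize

    img = rng.random(shape) * 100
    mask = rng.random(shape) < mask_p
    if not mask.any():
        mask[shape[0] // 2, shape[1] // 2] = True
    return img, mask, quantize(img, mask, n_grey)


@pytest.fixture
def random_slice_factory():
    return random_masked_slice
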