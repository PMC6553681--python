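import numpy as np
import pytest

from texrad.features.config import TextureConfig
from texrad.features.quantize import quantize
from texrad.features.wavelet import (
    haar_decompose,
    haar_reconstruct,
    masked_crop,
    wcf_features,
    wsf_features,
)
from texrad.features.glcm import glcm_features

from _oracles import oracle_glcm_features


def test_constant_block_level1():
    dec = haar_decompose(np.ones((2, 2)), 1)
    assert dec.subbands["LL1"] == pytest.approx(np.array([[2.0]]))
    for band in ("LH1", "HL1", "HH1"):
        assert dec.subbands[band] == pytest.approx(np.array([[0.0]]))


def test_energy_conservation(rng):
    img = rng.random((16, 12)) * 7
    dec = haar_decompose(img, 1)
    coeff_energy = sum((dec.subbands[f"{b}1"] ** 2).sum()
                       for b in ("LL", "LH", "HL", "HH"))
    assert coeff_energy == pytest.approx((img**2).sum(), rel=1e-9)


def test_perfect_reconstruction_even(rng):
    img = rng.random((8, 8))
    dec = haar_decompose(img, 3)
    assert np.abs(haar_reconstruct(dec) - img).max() < 1e-9


def test_perfect_reconstruction_odd(rng):
    img = rng.random((7, 9))
    dec = haar_decompose(img, 2)
    assert np.abs(haar_reconstruct(dec) - img).max() < 1e-9


def test_levels_decompose_approximation(rng):
    img = rng.random((16, 16))
    dec = haar_decompose(img, 3)
    assert dec.levels_completed == 3 and not dec.truncated
    assert dec.subbands["LL1"].shape == (8, 8)
    assert dec.subbands["LL3"].shape == (2, 2)
    # level 2 is the decomposition of LL1
    sub = haar_decompose(dec.subbands["LL1"], 1)
    np.testing.assert_allclose(sub.subbands["LL1"], dec.subbands["LL2"], atol=1e-12)


def test_too_small_image_truncates():
    dec = haar_decompose(np.ones((2, 2)), 3)
    assert dec.truncated and dec.levels_completed == 1


def test_masked_crop_mean_fill():
    img = np.array([[1.0, 2.0, 9.0], [3.0, 4.0, 9.0]])
    mask = np.array([[True, True, False], [True, True, False]])
    crop = masked_crop(img, mask)
    assert crop.shape == (2, 2)
    np.testing.assert_allclose(crop, [[1, 2], [3, 4]])
    mask2 = np.array([[True, False, False], [True, True, False]])
    crop2 = masked_crop(img, mask2)
    assert crop2[0, 1] == pytest.approx((1 + 3 + 4) / 3)


def test_wsf_emits_26_values(rng):
    img = rng.random((10, 10))
    feats = wsf_features(img, np.ones((10, 10), bool))
    assert len(feats) == 26


def test_wsf_constant_image():
    img = np.ones((8, 8))
    feats = wsf_features(img, np.ones((8, 8), bool))
    assert feats["Mean_OI"] == pytest.approx(1.0)
    assert feats["SD_OI"] == pytest.approx(0.0)
    assert feats["Mean_HH1"] == pytest.approx(0.0)


def test_wsf_scaling_linearity(rng):
    img = rng.random((12, 12)) * 5
    mask = rng.random((12, 12)) < 0.8
    mask[5, 5] = True
    f1 = wsf_features(img, mask)
    f2 = wsf_features(img * -3.0, mask)
    for name, v in f1.items():
        if not np.isfinite(v):
            continue
        factor = -3.0 if name.startswith("Mean") else 3.0
        assert f2[name] == pytest.approx(factor * v, abs=1e-9), name


def test_wsf_small_mask_truncated_levels_nan():
    mask = np.zeros((20, 20), bool)
    mask[3:5, 3:7] = True  # 2x4 crop: only one level possible
    rng = np.random.default_rng(3)
    feats = wsf_features(rng.random((20, 20)), mask)
    assert np.isfinite(feats["Mean_LL1"])
    assert not np.isfinite(feats["Mean_LL2"])
    assert not np.isfinite(feats["SD_HH3"])
    assert len(feats) == 26


def test_wcf_emits_24_values(rng):
    img = rng.random((10, 10))
    feats = wcf_features(img, np.ones((10, 10), bool))
    assert len(feats) == 24
    assert all(np.isfinite(v) for v in feats.values())


def test_wcf_constant_image_degenerate():
    feats = wcf_features(np.ones((8, 8)), np.ones((8, 8), bool))
    assert feats["Energy_HH1"] == pytest.approx(1.0)
    assert feats["Contrast_HH1"] == pytest.approx(0.0)
    assert not np.isfinite(feats["Correlation_HH1"])
    assert len(feats) == 24


def test_wcf_ll1_matches_glcm_oracle(rng):
    cfg = TextureConfig()
    img = rng.random((8, 8)) * 10
    mask = np.ones((8, 8), bool)
    feats = wcf_features(img, mask, cfg)
    dec = haar_decompose(masked_crop(img, mask), 1)
    ll1 = dec.subbands["LL1"]
    q = quantize(ll1, np.ones(ll1.shape, bool), cfg.n_grey)
    want = oracle_glcm_features(q.levels, q.mask, cfg.n_grey)
    for stat in ("Energy", "Contrast", "Correlation", "Homogeneity",
                 "Entropy", "Variance"):
        assert feats[f"{stat}_LL1"] == pytest.approx(want[stat], abs=1e-10), stat
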