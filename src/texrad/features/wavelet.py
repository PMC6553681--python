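"""Orthonormal 2D Haar decomposition and wavelet-derived texture features.

Two families are derived from the decomposition of the mask-filled crop of
the slice: subband mean/SD statistics (``WSF``) and Haralick statistics of
the quantized level-1 subbands (``WCF``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from texrad.features.config import TextureConfig
from texrad.features.glcm import GLCM_FEATURE_NAMES, glcm_features
from texrad.features.quantize import quantize

_BANDS = ("LL", "LH", "HL", "HH")
_SQRT2 = np.sqrt(2.0)

#: GLCM statistics retained for the wavelet co-occurrence family.
WCF_STATISTICS: tuple[str, ...] = (
    "Energy", "Contrast", "Correlation", "Homogeneity", "Entropy", "Variance",
)


@dataclass
class WaveletDecomposition:
    """Subbands ``LL_i/LH_i/HL_i/HH_i`` of a multi-level 2D Haar analysis.

    ``input_shapes[i]`` records the (pre-padding) shape fed to level i+1 so
    the inverse transform can crop back exactly.  ``truncated`` is set when
    the image became smaller than 2x2 before reaching the requested depth.
    """

    subbands: dict[str, np.ndarray]
    levels_requested: int
    levels_completed: int
    input_shapes: list[tuple[int, int]] = field(default_factory=list)

    @property
    def truncated(self) -> bool:
        return self.levels_completed < self.levels_requested


def _pad_even(x: np.ndarray) -> np.ndarray:
    """Edge-replicate odd dimensions to even length."""
    pr = x.shape[0] % 2
    pc = x.shape[1] % 2
    if pr or pc:
        x = np.pad(x, ((0, pr), (0, pc)), mode="edge")
    return x


def _haar_step(x: np.ndarray) -> dict[str, np.ndarray]:
    """One orthonormal Haar analysis step of an even-shaped 2D array.

    First letter of the band name is the filter along rows (axis 0), the
    second along columns (axis 1).
    """
    lo_r = (x[0::2, :] + x[1::2, :]) / _SQRT2
    hi_r = (x[0::2, :] - x[1::2, :]) / _SQRT2
    return {
        "LL": (lo_r[:, 0::2] + lo_r[:, 1::2]) / _SQRT2,
        "LH": (lo_r[:, 0::2] - lo_r[:, 1::2]) / _SQRT2,
        "HL": (hi_r[:, 0::2] + hi_r[:, 1::2]) / _SQRT2,
        "HH": (hi_r[:, 0::2] - hi_r[:, 1::2]) / _SQRT2,
    }


def _haar_step_inverse(bands: dict[str, np.ndarray]) -> np.ndarray:
    ll, lh, hl, hh = bands["LL"], bands["LH"], bands["HL"], bands["HH"]
    h, w = ll.shape
    lo_r = np.empty((h, 2 * w))
    hi_r = np.empty((h, 2 * w))
    lo_r[:, 0::2] = (ll + lh) / _SQRT2
    lo_r[:, 1::2] = (ll - lh) / _SQRT2
    hi_r[:, 0::2] = (hl + hh) / _SQRT2
    hi_r[:, 1::2] = (hl - hh) / _SQRT2
    x = np.empty((2 * h, 2 * w))
    x[0::2, :] = (lo_r + hi_r) / _SQRT2
    x[1::2, :] = (lo_r - hi_r) / _SQRT2
    return x


def haar_decompose(image: np.ndarray, levels: int) -> WaveletDecomposition:
    """Multi-level orthonormal 2D Haar analysis.

    Level i+1 decomposes the approximation ``LL_i``; odd dimensions are
    edge-replicated to even before each step.  If the approximation becomes
    smaller than 2x2 the decomposition stops early and is flagged.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite values")
    if levels < 1:
        raise ValueError("levels must be >= 1")

    subbands: dict[str, np.ndarray] = {}
    shapes: list[tuple[int, int]] = []
    current = image
    done = 0
    for i in range(1, levels + 1):
        if min(current.shape) < 2:
            break
        shapes.append(current.shape)
        step = _haar_step(_pad_even(current))
        for band in _BANDS:
            subbands[f"{band}{i}"] = step[band]
        current = step["LL"]
        done = i
    return WaveletDecomposition(subbands=subbands, levels_requested=levels,
                                levels_completed=done, input_shapes=shapes)


def haar_reconstruct(dec: WaveletDecomposition) -> np.ndarray:
    """Inverse of :func:`haar_decompose`; exact up to float rounding."""
    if dec.levels_completed == 0:
        raise ValueError("nothing to reconstruct")
    current = dec.subbands[f"LL{dec.levels_completed}"]
    for i in range(dec.levels_completed, 0, -1):
        bands = {b: dec.subbands[f"{b}{i}"] for b in _BANDS}
        bands = dict(bands, LL=current)
        x = _haar_step_inverse(bands)
        h, w = dec.input_shapes[i - 1]
        current = x[:h, :w]
    return current


def masked_crop(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Mask bounding-box crop with out-of-mask pixels set to the in-mask mean.

    Mean filling (rather than zero filling) avoids injecting a spurious
    intensity edge at the mask boundary before the wavelet analysis.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    sub_img = image[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    sub_msk = mask[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    fill = float(image[mask].mean())
    return np.where(sub_msk, sub_img, fill)


def wsf_names(levels: int = 3) -> tuple[str, ...]:
    names = ["Mean_OI", "SD_OI"]
    names += [f"Mean_{b}{i}" for i in range(1, levels + 1) for b in _BANDS]
    names += [f"SD_{b}{i}" for i in range(1, levels + 1) for b in _BANDS]
    return tuple(names)


def wcf_names() -> tuple[str, ...]:
    return tuple(f"{stat}_{b}1" for b in _BANDS for stat in WCF_STATISTICS)


def wsf_features(
    image: np.ndarray, mask: np.ndarray, cfg: TextureConfig | None = None
) -> dict[str, float]:
    """Mean/SD of in-mask intensities and of every Haar subband.

    2*(1 + 4*dwt_levels) values (26 at the default depth of 3); features of
    subbands the decomposition could not reach are NaN.  SDs are population
    standard deviations.
    """
    cfg = cfg or TextureConfig()
    out = {name: np.nan for name in wsf_names(cfg.dwt_levels)}
    inside = np.asarray(image, dtype=float)[np.asarray(mask, dtype=bool)]
    if inside.size == 0:
        return out
    out["Mean_OI"] = float(inside.mean())
    out["SD_OI"] = float(inside.std())
    dec = haar_decompose(masked_crop(image, mask), cfg.dwt_levels)
    for name, coeffs in dec.subbands.items():
        out[f"Mean_{name}"] = float(coeffs.mean())
        out[f"SD_{name}"] = float(coeffs.std())
    return out


def wcf_features(
    image: np.ndarray, mask: np.ndarray, cfg: TextureConfig | None = None
) -> dict[str, float]:
    """Six Haralick statistics of each quantized level-1 Haar subband.

    Each subband is quantized to ``n_grey`` uniform bins over its own
    min-max range; degenerate subbands yield NaN statistics.  Always emits
    24 values.
    """
    cfg = cfg or TextureConfig()
    out = {name: np.nan for name in wcf_names()}
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return out
    dec = haar_decompose(masked_crop(image, mask), 1)
    if dec.levels_completed < 1:
        return out
    full = {k: v for k, v in dec.subbands.items() if k.endswith("1")}
    for band_name, coeffs in full.items():
        q = quantize(coeffs, np.ones(coeffs.shape, dtype=bool), cfg.n_grey)
        stats = glcm_features(q, cfg)
        for stat in WCF_STATISTICS:
            out[f"{stat}_{band_name}"] = stats[stat]
    return out
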