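"""Rotation-invariant local binary patterns (8 neighbours, radius 1).

Each pixel whose full 3x3 neighbourhood lies inside the mask receives the
8-bit code ``sum_p s(g_p - g_c) 2^p`` with ``s(x) = 1`` iff ``x >= 0``,
computed on raw (unquantized) intensities.  Codes are canonicalised to the
minimum over the 8 circular bit rotations; exactly 36 canonical codes exist.
Features are the normalized 36-bin histogram plus the median, variance,
skewness and kurtosis of the canonical-code map (moment-based conventions,
kurtosis non-excess).
"""

from __future__ import annotations

import numpy as np

from texrad.features.config import TextureConfig

# circular neighbour order: (row, col) offsets, bit p at angle p*45 deg
_NEIGHBOUR_OFFSETS = (
    (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1),
)


def canonical_rotation(code: int, bits: int = 8) -> int:
    """Minimum of an integer code over its circular bit rotations."""
    mask = (1 << bits) - 1
    return min(((code >> k) | (code << (bits - k))) & mask for k in range(bits))


def canonical_codes(bits: int = 8) -> np.ndarray:
    """Sorted distinct canonical codes (36 values for 8 bits)."""
    return np.unique([canonical_rotation(c, bits) for c in range(1 << bits)])

_CANON_LUT = np.array([canonical_rotation(c) for c in range(256)], dtype=np.int64)
_CANON_CODES = canonical_codes()          # 36 sorted canonical codes
_CODE_TO_BIN = {int(c): k for k, c in enumerate(_CANON_CODES)}

LBP_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{i}" for i in range(1, len(_CANON_CODES) + 1)
) + ("Median", "Variance", "Skewness", "Kurtosis")


def lbp_code_map(image: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Canonical LBP code per pixel and the validity mask.

    A pixel is valid iff it and its 8 neighbours are all in-mask.  Codes of
    invalid pixels are set to -1.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")

    pad_img = np.pad(image, 1, mode="constant")
    pad_msk = np.pad(mask, 1, mode="constant", constant_values=False)
    h, w = image.shape
    centre = pad_img[1:h + 1, 1:w + 1]

    raw = np.zeros((h, w), dtype=np.int64)
    valid = mask.copy()
    for p, (dr, dc) in enumerate(_NEIGHBOUR_OFFSETS):
        nb = pad_img[1 + dr:1 + dr + h, 1 + dc:1 + dc + w]
        nb_in = pad_msk[1 + dr:1 + dr + h, 1 + dc:1 + dc + w]
        valid &= nb_in
        raw |= (nb >= centre).astype(np.int64) << p

    codes = np.where(valid, _CANON_LUT[raw], -1)
    return codes, valid


def lbp_features(
    image: np.ndarray, mask: np.ndarray, cfg: TextureConfig | None = None
) -> dict[str, float]:
    """36 normalized histogram bins + 4 statistics of the canonical-code map.

    All 40 values are NaN when no valid pixel exists.
    """
    codes, valid = lbp_code_map(image, mask)
    vals = codes[valid].astype(float)
    if vals.size == 0:
        return {name: np.nan for name in LBP_FEATURE_NAMES}

    hist = np.zeros(len(_CANON_CODES))
    bins = np.searchsorted(_CANON_CODES, codes[valid])
    np.add.at(hist, bins, 1.0)
    hist /= vals.size

    m = vals.mean()
    m2 = ((vals - m) ** 2).mean()
    m3 = ((vals - m) ** 3).mean()
    m4 = ((vals - m) ** 4).mean()
    skew = m3 / m2**1.5 if m2 > 0 else np.nan
    kurt = m4 / m2**2 if m2 > 0 else np.nan

    out = {f"{i + 1}": float(hist[i]) for i in range(len(_CANON_CODES))}
    out["Median"] = float(np.median(vals))
    out["Variance"] = float(m2)
    out["Skewness"] = float(skew)
    out["Kurtosis"] = float(kurt)
    return out
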