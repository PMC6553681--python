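"""Grey-level co-occurrence matrix (Haralick) statistics.

Matrices are built per direction from ordered pixel pairs whose two members
both lie inside the mask, symmetrised by adding the transpose, and
normalized.  Statistics are computed per direction and then averaged over
directions (feature averaging, not matrix averaging) for rotation
invariance.
"""

from __future__ import annotations

import numpy as np

from texrad.features.config import TextureConfig
from texrad.features.quantize import QuantizedSlice

GLCM_FEATURE_NAMES: tuple[str, ...] = (
    "Energy",
    "Contrast",
    "Correlation",
    "Variance",
    "Homogeneity",
    "SumAverage",
    "SumVariance",
    "SumEntropy",
    "Entropy",
    "DiffVariance",
    "DiffEntropy",
    "FIMC",
    "SIMC",
)

# (row, col) offsets of the forward neighbour for each angle, image convention
# (row axis points down): 0 deg is to the right, angles increase CCW.
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def cooccurrence_matrix(q: QuantizedSlice, angle: int, distance: int = 1) -> np.ndarray:
    """Symmetrised, normalized Ng x Ng co-occurrence matrix for one direction.

    Returns the all-zero matrix when the direction admits no in-mask pair.
    """
    dr, dc = _OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    lev, mask, ng = q.levels, q.mask, q.n_grey
    h, w = lev.shape

    r0s, r0e = max(0, -dr), min(h, h - dr)
    c0s, c0e = max(0, -dc), min(w, w - dc)
    a = lev[r0s:r0e, c0s:c0e]
    b = lev[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
    valid = mask[r0s:r0e, c0s:c0e] & mask[r0s + dr:r0e + dr, c0s + dc:c0e + dc]

    counts = np.bincount(
        ((a[valid] - 1) * ng + (b[valid] - 1)).ravel(), minlength=ng * ng
    ).reshape(ng, ng).astype(float)
    counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        return counts
    return counts / total


def _xlogx(p: np.ndarray) -> np.ndarray:
    """p * log(p) with the 0 log 0 = 0 convention (natural log)."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def haralick_statistics(p: np.ndarray) -> dict[str, float]:
    """The 13 Haralick statistics of one normalized symmetric GLCM.

    Statistics that are undefined on a degenerate matrix (e.g. correlation
    of a constant region) are returned as NaN.
    """
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.dot(i, px))
    mu_y = float(np.dot(i, py))
    var_x = float(np.dot((i - mu_x) ** 2, px))
    var_y = float(np.dot((i - mu_y) ** 2, py))

    # distributions of i+j (2..2Ng) and |i-j| (0..Ng-1)
    idx = np.arange(ng)
    p_sum = np.bincount(np.add.outer(idx, idx).ravel(), weights=p.ravel(),
                        minlength=2 * ng - 1)
    p_diff = np.bincount(np.abs(np.subtract.outer(idx, idx)).ravel(),
                         weights=p.ravel(), minlength=ng)

    energy = float((p**2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    if var_x > 0 and var_y > 0:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_y) / np.sqrt(var_x * var_y))
    else:
        correlation = np.nan
    variance = float((((ii - mu_x) ** 2) * p).sum())
    homogeneity = float((p / (1.0 + (ii - jj) ** 2)).sum())

    ks = np.arange(2, 2 * ng + 1, dtype=float)
    sum_average = float(np.dot(ks, p_sum))
    sum_variance = float(np.dot((ks - sum_average) ** 2, p_sum))
    sum_entropy = float(-_xlogx(p_sum).sum())

    entropy = float(-_xlogx(p).sum())

    kd = np.arange(ng, dtype=float)
    diff_mean = float(np.dot(kd, p_diff))
    diff_variance = float(np.dot((kd - diff_mean) ** 2, p_diff))
    diff_entropy = float(-_xlogx(p_diff).sum())

    # information measures of correlation
    pxy = np.outer(px, py)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_pxy = np.where(pxy > 0, np.log(pxy), 0.0)
    hxy1 = float(-(np.where(p > 0, p * log_pxy, 0.0)).sum())
    hxy2 = float(-_xlogx(pxy).sum())
    hx = float(-_xlogx(px).sum())
    hy = float(-_xlogx(py).sum())
    denom = max(hx, hy)
    fimc = (entropy - hxy1) / denom if denom > 0 else np.nan
    simc = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    return {
        "Energy": energy,
        "Contrast": contrast,
        "Correlation": correlation,
        "Variance": variance,
        "Homogeneity": homogeneity,
        "SumAverage": sum_average,
        "SumVariance": sum_variance,
        "SumEntropy": sum_entropy,
        "Entropy": entropy,
        "DiffVariance": diff_variance,
        "DiffEntropy": diff_entropy,
        "FIMC": fimc,
        "SIMC": simc,
    }


def average_over_directions(per_direction: list[dict[str, float]],
                            names: tuple[str, ...]) -> dict[str, float]:
    """Per-feature mean over directions, ignoring non-finite directions.

    A feature with no finite value in any direction stays NaN.
    """
    out = {}
    for name in names:
        vals = [d[name] for d in per_direction if np.isfinite(d[name])]
        out[name] = float(np.mean(vals)) if vals else np.nan
    return out


def glcm_features(q: QuantizedSlice, cfg: TextureConfig | None = None) -> dict[str, float]:
    """The 13 direction-averaged Haralick features of a quantized slice.

    When every direction lacks a co-occurring in-mask pair, all features are
    NaN (never an exception): downstream aggregation treats them as invalid.
    """
    cfg = cfg or TextureConfig()
    per_dir = []
    for angle in cfg.directions:
        p = cooccurrence_matrix(q, angle, cfg.distance)
        if p.sum() == 0:
            continue
        per_dir.append(haralick_statistics(p))
    if not per_dir:
        return {name: np.nan for name in GLCM_FEATURE_NAMES}
    return average_over_directions(per_dir, GLCM_FEATURE_NAMES)
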