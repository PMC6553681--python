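"""Grey-level run-length matrix statistics.

A run is a maximal sequence of equal-level in-mask pixels along a scan
direction; mask boundaries break runs.  Features are computed per direction
and averaged over directions.  The run-percentage denominator is the
in-mask pixel count.
"""

from __future__ import annotations

import numpy as np

from texrad.features.config import TextureConfig
from texrad.features.glcm import average_over_directions
from texrad.features.quantize import OUTSIDE, QuantizedSlice

GLRLM_FEATURE_NAMES: tuple[str, ...] = (
    "SRE",
    "LRE",
    "GLN",
    "RLN",
    "RP",
    "LGRE",
    "HGRE",
    "SRLGE",
    "SRHGE",
    "LRLGE",
    "LRHGE",
)


def _scan_lines(seq: np.ndarray, angle: int) -> list[np.ndarray]:
    """The pixel lines of a 2D array along one of the four scan angles."""
    if angle == 0:
        return list(seq)
    if angle == 90:
        return list(seq.T)
    if angle == 45:  # anti-diagonals
        flipped = np.fliplr(seq)
        return [np.diagonal(flipped, off) for off in range(-seq.shape[0] + 1, seq.shape[1])]
    if angle == 135:  # main diagonals
        return [np.diagonal(seq, off) for off in range(-seq.shape[0] + 1, seq.shape[1])]
    raise ValueError(f"unsupported angle {angle}")


def _run_values_lengths(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Values and lengths of the maximal constant runs of a 1D array."""
    n = a.size
    if n == 0:
        return np.empty(0, dtype=a.dtype), np.empty(0, dtype=np.int64)
    change = np.flatnonzero(a[1:] != a[:-1])
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [n - 1]))
    return a[starts], ends - starts + 1


def run_length_matrix(q: QuantizedSlice, angle: int) -> np.ndarray:
    """Ng x Lmax run-count matrix for one direction (Lmax = longest side)."""
    lev = np.where(q.mask, q.levels, OUTSIDE)
    lmax = max(lev.shape)
    counts = np.zeros((q.n_grey, lmax), dtype=float)
    # one concatenated pass: join lines with a separator that breaks runs
    sep = np.array([OUTSIDE], dtype=lev.dtype)
    lines = _scan_lines(lev, angle)
    joined = np.concatenate([x for line in lines for x in (line, sep)])
    values, lengths = _run_values_lengths(joined)
    keep = values != OUTSIDE
    values, lengths = values[keep], lengths[keep]
    if values.size:
        np.add.at(counts, (values - 1, lengths - 1), 1.0)
    return counts


def run_length_statistics(counts: np.ndarray, n_pixels: int) -> dict[str, float]:
    """The 11 run-length statistics of one run-count matrix."""
    n_runs = counts.sum()
    if n_runs == 0:
        return {name: np.nan for name in GLRLM_FEATURE_NAMES}
    ng, lmax = counts.shape
    i2 = np.arange(1, ng + 1, dtype=float)[:, None] ** 2
    j2 = np.arange(1, lmax + 1, dtype=float)[None, :] ** 2
    return {
        "SRE": float((counts / j2).sum() / n_runs),
        "LRE": float((counts * j2).sum() / n_runs),
        "GLN": float((counts.sum(axis=1) ** 2).sum() / n_runs),
        "RLN": float((counts.sum(axis=0) ** 2).sum() / n_runs),
        "RP": float(n_runs / n_pixels),
        "LGRE": float((counts / i2).sum() / n_runs),
        "HGRE": float((counts * i2).sum() / n_runs),
        "SRLGE": float((counts / (i2 * j2)).sum() / n_runs),
        "SRHGE": float((counts * i2 / j2).sum() / n_runs),
        "LRLGE": float((counts * j2 / i2).sum() / n_runs),
        "LRHGE": float((counts * i2 * j2).sum() / n_runs),
    }


def glrlm_features(q: QuantizedSlice, cfg: TextureConfig | None = None) -> dict[str, float]:
    """The 11 direction-averaged run-length features of a quantized slice.

    All-NaN (never an exception) when no direction contains a run.
    """
    cfg = cfg or TextureConfig()
    n_pixels = int(q.mask.sum())
    per_dir = []
    for angle in cfg.directions:
        counts = run_length_matrix(q, angle)
        if counts.sum() == 0:
            continue
        per_dir.append(run_length_statistics(counts, n_pixels))
    if not per_dir:
        return {name: np.nan for name in GLRLM_FEATURE_NAMES}
    return average_over_directions(per_dir, GLRLM_FEATURE_NAMES)
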