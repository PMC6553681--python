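"""Uniform grey-level quantization of masked slices."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Level assigned to out-of-mask pixels in a quantized slice.
OUTSIDE = 0


class EmptyRegionError(ValueError):
    """Raised when an operation requires at least one in-mask pixel."""


@dataclass(frozen=True)
class QuantizedSlice:
    """A 2D slice quantized to levels ``1..n_grey`` inside the mask.

    Out-of-mask pixels carry the sentinel level ``OUTSIDE`` (0).
    """

    levels: np.ndarray
    mask: np.ndarray
    n_grey: int

    def __post_init__(self) -> None:
        if self.levels.shape != self.mask.shape:
            raise ValueError("levels and mask shapes differ")
        inside = self.levels[self.mask]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_grey):
            raise ValueError("in-mask level outside [1, n_grey]")


def quantize(
    image: np.ndarray,
    mask: np.ndarray,
    n_grey: int,
    value_range: tuple[float, float] | None = None,
) -> QuantizedSlice:
    """Uniformly quantize a masked 2D slice to ``n_grey`` grey levels.

    Bins are uniform over ``value_range`` (default: in-mask min-max of this
    slice).  The top of the range maps to level ``n_grey``; a degenerate
    (constant) range maps every in-mask pixel to level 1.

    Parameters
    ----------
    image : 2D float array of finite intensities.
    mask : 2D boolean array, same shape, with at least one True pixel.
    n_grey : number of grey levels (>= 2).
    value_range : optional (low, high) reference range, e.g. the in-mask
        range of the whole parent volume so all slices share one grey scale.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise EmptyRegionError("mask has no true pixel")
    if not np.isfinite(image[mask]).all():
        raise ValueError("non-finite intensity inside mask")
    if n_grey < 2:
        raise ValueError("n_grey must be >= 2")

    if value_range is None:
        lo, hi = float(image[mask].min()), float(image[mask].max())
    else:
        lo, hi = map(float, value_range)
        if hi < lo:
            raise ValueError("value_range high < low")

    levels = np.full(image.shape, OUTSIDE, dtype=np.int64)
    if hi == lo:
        levels[mask] = 1
    else:
        scaled = (image[mask] - lo) / (hi - lo)
        lev = np.floor(scaled * n_grey).astype(np.int64) + 1
        levels[mask] = np.clip(lev, 1, n_grey)
    return QuantizedSlice(levels=levels, mask=mask, n_grey=n_grey)
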