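"""Full per-slice descriptor set and its median aggregation over slices.

The 114 descriptors partition into five families:

=======  =====
GLCM        13
GLRLM       11
LBP         40
WSF         26
WCF         24
=======  =====

3D descriptors for a masked volume are obtained by extracting the 2D set
from every contributing slice and taking, per feature, the median over the
slices where that feature is finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from texrad.features.config import TextureConfig
from texrad.features.glcm import GLCM_FEATURE_NAMES, glcm_features
from texrad.features.glrlm import GLRLM_FEATURE_NAMES, glrlm_features
from texrad.features.lbp import LBP_FEATURE_NAMES, lbp_features
from texrad.features.quantize import quantize
from texrad.features.wavelet import wcf_features, wsf_features, wcf_names, wsf_names

FAMILY_SIZES = {"GLCM": 13, "GLRLM": 11, "LBP": 40, "WSF": 26, "WCF": 24}


def feature_names(cfg: TextureConfig | None = None) -> tuple[str, ...]:
    """The 114 feature names, in stable serialization order."""
    cfg = cfg or TextureConfig()
    names = [f"GLCM_{n}" for n in GLCM_FEATURE_NAMES]
    names += [f"GLRLM_{n}" for n in GLRLM_FEATURE_NAMES]
    names += [f"LBP_{n}" for n in LBP_FEATURE_NAMES]
    names += [f"WSF_{n}" for n in wsf_names(cfg.dwt_levels)]
    names += [f"WCF_{n}" for n in wcf_names()]
    return tuple(names)


@dataclass(frozen=True)
class FeatureVector:
    """Ordered named descriptor values with per-feature validity flags."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        if len(self.values) != len(set(self.values)):
            raise ValueError("duplicate feature names")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.values)

    @property
    def validity(self) -> dict[str, bool]:
        return {k: bool(np.isfinite(v)) for k, v in self.values.items()}

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=float)

    def __len__(self) -> int:
        return len(self.values)


def extract_slice_features(
    image: np.ndarray,
    mask: np.ndarray,
    cfg: TextureConfig | None = None,
    value_range: tuple[float, float] | None = None,
) -> FeatureVector:
    """The full 2D descriptor set of one masked slice.

    ``value_range`` is the quantization reference range (in-mask volume
    min-max under the default range policy); LBP and WSF operate on raw
    intensities.
    """
    cfg = cfg or TextureConfig()
    q = quantize(image, mask, cfg.n_grey, value_range)
    values: dict[str, float] = {}
    values.update({f"GLCM_{k}": v for k, v in glcm_features(q, cfg).items()})
    values.update({f"GLRLM_{k}": v for k, v in glrlm_features(q, cfg).items()})
    values.update({f"LBP_{k}": v for k, v in lbp_features(image, mask, cfg).items()})
    values.update({f"WSF_{k}": v for k, v in wsf_features(image, mask, cfg).items()})
    values.update({f"WCF_{k}": v for k, v in wcf_features(image, mask, cfg).items()})
    return FeatureVector(values=values)


def median_aggregate(slice_vectors: list[FeatureVector]) -> FeatureVector:
    """Per-feature median over the slices where that feature is finite."""
    if not slice_vectors:
        raise ValueError("no slice vectors to aggregate")
    names = slice_vectors[0].names
    stacked = np.array([v.as_array() for v in slice_vectors])
    out: dict[str, float] = {}
    for j, name in enumerate(names):
        col = stacked[:, j]
        finite = col[np.isfinite(col)]
        out[name] = float(np.median(finite)) if finite.size else np.nan
    return FeatureVector(values=out)


def extract_volume_features(
    volume, cfg: TextureConfig | None = None, slice_axis: int = 2
) -> FeatureVector:
    """3D descriptors of a masked volume by slice-wise extraction + median.

    Slices with fewer than ``cfg.min_mask_pixels`` in-mask pixels are
    skipped.  When no slice contributes, an all-NaN vector is returned
    (never an exception); its validity flags are all False.

    Parameters
    ----------
    volume : object with ``intensities`` and ``mask`` 3D arrays
        (e.g. :class:`texrad.synthetic.VolumeWithMask`).
    cfg : extraction configuration.
    slice_axis : array axis along which 2D slices are taken.
    """
    cfg = cfg or TextureConfig()
    intensities = np.asarray(volume.intensities, dtype=float)
    mask = np.asarray(volume.mask, dtype=bool)
    if intensities.shape != mask.shape:
        raise ValueError("intensities and mask shapes differ")
    if intensities.ndim != 3:
        raise ValueError("expected a 3D volume")

    intensities = np.moveaxis(intensities, slice_axis, 0)
    mask = np.moveaxis(mask, slice_axis, 0)

    value_range = None
    if cfg.range_policy == "volume" and mask.any():
        inside = intensities[mask]
        value_range = (float(inside.min()), float(inside.max()))

    vectors = [
        extract_slice_features(img, msk, cfg, value_range)
        for img, msk in zip(intensities, mask)
        if int(msk.sum()) >= cfg.min_mask_pixels
    ]
    if not vectors:
        return FeatureVector(values={n: np.nan for n in feature_names(cfg)})
    return median_aggregate(vectors)
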