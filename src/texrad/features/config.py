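"""Extraction configuration shared by all texture families."""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass(frozen=True)
class TextureConfig:
    """Parameters of the per-slice texture extraction.

    Attributes
    ----------
    n_grey :
        Number of grey levels for uniform quantization (matrix methods only;
        the LBP operator works on raw intensities).
    distance :
        Co-occurrence pixel offset distance in pixels.
    directions :
        Angles (degrees) over which matrix-derived statistics are averaged.
    lbp_points, lbp_radius :
        Neighbourhood of the local binary pattern operator.  Only the
        classic 8-point, radius-1 configuration is supported: the canonical
        rotation-invariant histogram has exactly 36 bins for 8 bits.
    dwt_levels :
        Depth of the Haar decomposition used by the wavelet statistics.
    range_policy :
        Reference range for quantization: ``"volume"`` uses the in-mask
        min-max over the whole volume so all slices share one grey scale,
        ``"slice"`` re-derives the range per slice.
    min_mask_pixels :
        Slices with fewer in-mask pixels than this do not contribute to the
        3D aggregation.
    """

    n_grey: int = 32
    distance: int = 1
    directions: tuple[int, ...] = (0, 45, 90, 135)
    lbp_points: int = 8
    lbp_radius: int = 1
    dwt_levels: int = 3
    wavelet_family: str = "haar"
    range_policy: str = "volume"
    min_mask_pixels: int = 16

    def __post_init__(self) -> None:
        if self.n_grey < 2:
            raise ValueError(f"n_grey must be >= 2, got {self.n_grey}")
        if self.distance < 1:
            raise ValueError(f"distance must be >= 1, got {self.distance}")
        if not self.directions:
            raise ValueError("directions must be non-empty")
        if self.lbp_points != 8 or self.lbp_radius != 1:
            raise ValueError("only lbp_points=8, lbp_radius=1 is supported")
        if self.dwt_levels < 1:
            raise ValueError(f"dwt_levels must be >= 1, got {self.dwt_levels}")
        if self.wavelet_family != "haar":
            raise ValueError(f"unsupported wavelet family {self.wavelet_family!r}")
        if self.range_policy not in ("volume", "slice"):
            raise ValueError(f"range_policy must be 'volume' or 'slice', got {self.range_policy!r}")
        if self.min_mask_pixels < 1:
            raise ValueError("min_mask_pixels must be >= 1")

    def to_dict(self) -> dict:
        return {f.name: list(v) if isinstance(v := getattr(self, f.name), tuple) else v
                for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "TextureConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown TextureConfig keys: {sorted(unknown)}")
        d = dict(d)
        if "directions" in d:
            d["directions"] = tuple(d["directions"])
        return cls(**d)
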