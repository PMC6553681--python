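"""Two-class phantom cohorts with controllable texture contrast.

Class differences are induced through the *spatial structure* of a seeded
Gaussian random field — its smoothing scale (correlation length) and a
local-contrast multiplier — not through mean intensity alone, so that
texture descriptors rather than first-order statistics carry the signal.

Cohorts come with a covariate table: one covariate can be generated with a
configurable true correlation to the class-separating texture parameter;
the remaining covariates are independent noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

MASK_KINDS = ("blob", "shell", "scatter")


class InvalidSpecError(ValueError):
    """Raised for phantom specifications violating their invariants."""


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of a two-class phantom cohort.

    ``effect_size = 0`` makes both classes share identical generative
    parameters; larger values increase the separation of the smoothing
    scale and the local-contrast multiplier between classes.
    """

    volume_shape: tuple[int, int, int] = (64, 64, 24)
    mask_kind: str = "blob"
    mask_fraction: float = 0.1
    base_intensity: float = 100.0
    noise_sd: float = 15.0
    smoothing_scale: float = 1.0
    contrast_mult: float = 1.0
    effect_size: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.volume_shape) != 3 or any(s < 8 for s in self.volume_shape):
            raise InvalidSpecError(f"volume_shape components must be >= 8, got {self.volume_shape}")
        if self.mask_kind not in MASK_KINDS:
            raise InvalidSpecError(f"mask_kind must be one of {MASK_KINDS}")
        if not (0 < self.mask_fraction <= 0.5):
            raise InvalidSpecError("mask_fraction must be in (0, 0.5]")
        if self.effect_size < 0:
            raise InvalidSpecError("effect_size must be >= 0")
        if self.noise_sd < 0 or self.smoothing_scale <= 0 or self.contrast_mult <= 0:
            raise InvalidSpecError("noise_sd must be >= 0; scales must be > 0")

    def class_params(self, class_label: int) -> tuple[float, float]:
        """(smoothing_scale, contrast_mult) of one class.

        Class 1 gets a longer correlation length and higher local contrast,
        scaled by ``effect_size``; at 0 both classes coincide.
        """
        if class_label not in (0, 1):
            raise InvalidSpecError(f"class_label must be 0 or 1, got {class_label}")
        if class_label == 0:
            return self.smoothing_scale, self.contrast_mult
        return (self.smoothing_scale * (1.0 + 0.75 * self.effect_size),
                self.contrast_mult * (1.0 + self.effect_size))


@dataclass(frozen=True)
class VolumeWithMask:
    """A 3D grey-level volume with a co-registered binary ROI mask."""

    intensities: np.ndarray
    mask: np.ndarray
    subject_id: str
    sequence_tag: str = "SIM"
    tissue_tag: str = "ROI"

    def __post_init__(self) -> None:
        if self.intensities.shape != self.mask.shape:
            raise ValueError("intensities and mask shapes differ")
        if not self.mask.any():
            raise ValueError("mask has no true voxel")
        if not np.isfinite(self.intensities).all():
            raise ValueError("non-finite intensities")


def _smooth_unit_field(shape, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian-smoothed white noise rescaled to zero mean, unit SD."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    sd = f.std()
    if sd == 0:
        return np.zeros(shape)
    return (f - f.mean()) / sd


def generate_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Binary ROI mask with an expected in-mask fraction ``mask_fraction``.

    ``blob``: a single smooth irregular region; ``shell``: a band around a
    blob boundary; ``scatter``: many small clusters (the small-lesion
    failure path).
    """
    shape = spec.volume_shape
    f = spec.mask_fraction
    if spec.mask_kind == "scatter":
        field = _smooth_unit_field(shape, 0.8, rng)
        mask = field >= np.quantile(field, 1.0 - f)
    elif spec.mask_kind == "blob":
        sigma = max(2.0, min(shape) / 6.0)
        field = _smooth_unit_field(shape, sigma, rng)
        mask = field >= np.quantile(field, 1.0 - f)
    else:  # shell
        sigma = max(2.0, min(shape) / 6.0)
        field = _smooth_unit_field(shape, sigma, rng)
        lo = np.quantile(field, 1.0 - f)
        inner = np.quantile(field, 1.0 - f / 2.0)
        mask = (field >= lo) & (field < inner)
    if not mask.any():  # quantile ties can empty tiny masks
        mask.flat[int(np.argmax(field))] = True
    return mask


def generate_phantom(
    spec: PhantomSpec,
    class_label: int,
    seed: int,
    subject_id: str | None = None,
    contrast_jitter: float = 1.0,
) -> VolumeWithMask:
    """One phantom volume drawn from the given class's texture parameters.

    Deterministic: identical ``(spec, class_label, seed)`` yields
    bit-identical voxel arrays.  ``contrast_jitter`` multiplies the class
    contrast (used by cohorts to give subjects individual latent values).
    """
    smooth, contrast = spec.class_params(class_label)
    contrast *= contrast_jitter
    rng = np.random.default_rng([spec.seed, int(seed), int(class_label)])
    mask = generate_mask(spec, rng)
    texture = _smooth_unit_field(spec.volume_shape, smooth, rng)
    intensities = spec.base_intensity + spec.noise_sd * contrast * texture
    np.clip(intensities, 0.0, None, out=intensities)
    return VolumeWithMask(
        intensities=intensities,
        mask=mask,
        subject_id=subject_id or f"S{seed:04d}",
        tissue_tag=spec.mask_kind.upper(),
    )


def generate_covariates(
    latent: np.ndarray,
    true_correlation: float,
    n_noise: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One covariate correlated ``true_correlation`` with ``latent`` plus noise columns."""
    if not (-1.0 <= true_correlation <= 1.0):
        raise ValueError("true_correlation must be in [-1, 1]")
    n = len(latent)
    z = np.asarray(latent, dtype=float)
    sd = z.std()
    z = (z - z.mean()) / sd if sd > 0 else np.zeros(n)
    rho = true_correlation
    cov0 = rho * z + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    data = {"cov_signal": cov0}
    for j in range(n_noise):
        data[f"cov_noise{j + 1}"] = rng.standard_normal(n)
    return pd.DataFrame(data)


def generate_cohort(
    spec: PhantomSpec,
    n_per_class: int,
    base_seed: int = 0,
    covariate_correlation: float = 0.0,
    n_noise_covariates: int = 3,
) -> tuple[list[tuple[VolumeWithMask, int]], pd.DataFrame]:
    """A balanced two-class cohort of ``2 * n_per_class`` phantom subjects.

    Each subject's local-contrast multiplier is jittered around its class
    value; the signal covariate is generated with the requested true
    correlation to that realized multiplier.
    """
    if n_per_class < 1:
        raise InvalidSpecError("n_per_class must be >= 1")
    rng = np.random.default_rng([spec.seed, int(base_seed), 2**31])
    subjects: list[tuple[VolumeWithMask, int]] = []
    latents = []
    idx = 0
    for label in (0, 1):
        for _ in range(n_per_class):
            jitter = float(rng.uniform(0.9, 1.1))
            vol = generate_phantom(
                spec, label, seed=base_seed * 100003 + idx,
                subject_id=f"S{idx:04d}", contrast_jitter=jitter,
            )
            _, contrast = spec.class_params(label)
            latents.append(contrast * jitter)
            subjects.append((vol, label))
            idx += 1
    covariates = generate_covariates(
        np.array(latents), covariate_correlation, n_noise_covariates, rng
    )
    covariates.insert(0, "subject_id", [v.subject_id for v, _ in subjects])
    covariates.insert(1, "label", [lab for _, lab in subjects])
    return subjects, covariates
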