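"""Standard-format I/O: NIfTI volumes, CSV manifests/tables, YAML config.

Coordinate convention is voxel-index space only: volume/mask affines are
checked for agreement but never resampled — a mismatch is an error.  Every
CSV artifact starts with a ``# config_hash: ...`` comment line so outputs
are traceable to the configuration that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from texrad.evaluate import CVPlan, ModelGrid, RankingConfig
from texrad.features.config import TextureConfig
from texrad.pipeline import (
    DEFAULT_NZV_FREQ_RATIO,
    DEFAULT_NZV_UNIQUE_PCT,
    FeatureTable,
)
from texrad.synthetic import PhantomSpec, VolumeWithMask


class ManifestError(ValueError):
    """Raised for unreadable or inconsistent study manifests."""


@dataclass(frozen=True)
class PhantomRunConfig:
    """Cohort-level simulation settings wrapped around a PhantomSpec."""

    spec: PhantomSpec = PhantomSpec()
    n_per_class: int = 10
    covariate_correlation: float = 0.0
    n_noise_covariates: int = 3


@dataclass(frozen=True)
class CleaningConfig:
    nzv_freq_ratio: float = DEFAULT_NZV_FREQ_RATIO
    nzv_unique_pct: float = DEFAULT_NZV_UNIQUE_PCT


@dataclass(frozen=True)
class ScreenConfig:
    alpha: float = 0.05
    family: str = "per_dataset"


@dataclass(frozen=True)
class RunConfig:
    """Full run configuration; round-trips losslessly through YAML."""

    seed: int = 0
    out_dir: str = "texrad_run"
    slice_axis: int = 2
    phantom: PhantomRunConfig = PhantomRunConfig()
    texture: TextureConfig = TextureConfig()
    cleaning: CleaningConfig = CleaningConfig()
    screen: ScreenConfig = ScreenConfig()
    cv: CVPlan = CVPlan()
    grid: ModelGrid = ModelGrid()
    ranking: RankingConfig = RankingConfig()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom"]["spec"] = dataclasses.asdict(self.phantom.spec)
        return _tuples_to_lists(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sections = {
            "phantom": _phantom_from_dict,
            "texture": TextureConfig.from_dict,
            "cleaning": lambda s: _strict(CleaningConfig, s),
            "screen": lambda s: _strict(ScreenConfig, s),
            "cv": lambda s: _strict(CVPlan, s),
            "grid": lambda s: _strict(ModelGrid, s, tuple_keys=("svm_C", "rf_mtry")),
            "ranking": lambda s: _strict(RankingConfig, s),
        }
        kwargs = {}
        for key, builder in sections.items():
            if key in d:
                kwargs[key] = builder(d.pop(key))
        scalar_keys = {"seed", "out_dir", "slice_axis"}
        unknown = set(d) - scalar_keys
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(d)
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_tuples_to_lists(v) for v in obj]
    return obj


def _strict(cls, section: dict, tuple_keys: tuple[str, ...] = ()):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    section = dict(section)
    for key in tuple_keys:
        if key in section:
            section[key] = tuple(section[key])
    return cls(**section)


def _phantom_from_dict(section: dict) -> PhantomRunConfig:
    section = dict(section)
    spec_dict = dict(section.pop("spec", {}))
    if "volume_shape" in spec_dict:
        spec_dict["volume_shape"] = tuple(spec_dict["volume_shape"])
    spec = _strict(PhantomSpec, spec_dict)
    return _strict(PhantomRunConfig, dict(section, spec=spec))


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# NIfTI cohorts and manifests


def save_volume(vol: VolumeWithMask, directory: Path) -> tuple[Path, Path]:
    """Write `<subject>_<sequence>.nii.gz` + its `..._<tissue>_mask.nii.gz`."""
    directory.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    vol_path = directory / f"{vol.subject_id}_{vol.sequence_tag}.nii.gz"
    mask_path = directory / f"{vol.subject_id}_{vol.sequence_tag}_{vol.tissue_tag}_mask.nii.gz"
    nib.save(nib.Nifti1Image(vol.intensities.astype(np.float32), affine), vol_path)
    nib.save(nib.Nifti1Image(vol.mask.astype(np.uint8), affine), mask_path)
    return vol_path, mask_path


def save_cohort(
    subjects: list[tuple[VolumeWithMask, int]],
    covariates: pd.DataFrame,
    out_dir: str | Path,
    config_hash: str = "",
) -> Path:
    """Write NIfTI pairs plus a CSV manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    rows = []
    for vol, label in subjects:
        vol_path, mask_path = save_volume(vol, out_dir / "images")
        rows.append({
            "subject_id": vol.subject_id,
            "label": int(label),
            "sequence": vol.sequence_tag,
            "tissue": vol.tissue_tag,
            "volume_path": str(vol_path),
            "mask_path": str(mask_path),
        })
    manifest = pd.DataFrame(rows)
    cov = covariates.drop(columns=["label"], errors="ignore")
    manifest = manifest.merge(cov, on="subject_id", how="left")
    path = out_dir / "manifest.csv"
    write_csv(manifest, path, config_hash, index=False)
    return path


def load_study(
    manifest_path: str | Path,
) -> tuple[list[VolumeWithMask], dict[str, int], pd.DataFrame]:
    """Load a manifest's volumes/masks with shape and affine checks.

    Masks are binarised at > 0.  Errors name the offending subject.
    """
    manifest = read_csv(manifest_path)
    required = {"subject_id", "label", "sequence", "tissue", "volume_path", "mask_path"}
    missing = required - set(manifest.columns)
    if missing:
        raise ManifestError(f"manifest missing columns: {sorted(missing)}")

    volumes: list[VolumeWithMask] = []
    labels: dict[str, int] = {}
    for row in manifest.itertuples(index=False):
        sid = str(row.subject_id)
        for path in (row.volume_path, row.mask_path):
            if not Path(path).exists():
                raise ManifestError(f"subject {sid}: missing file {path}")
        img = nib.load(row.volume_path)
        msk = nib.load(row.mask_path)
        if img.shape != msk.shape:
            raise ManifestError(
                f"subject {sid}: volume shape {img.shape} != mask shape {msk.shape}")
        if not np.allclose(img.affine, msk.affine, atol=1e-4):
            raise ManifestError(f"subject {sid}: volume/mask affine mismatch")
        intensities = np.asarray(img.dataobj, dtype=float)
        mask = np.asarray(msk.dataobj) > 0
        if not mask.any():
            raise ManifestError(f"subject {sid}: mask has no voxels")
        label = int(row.label)
        if label not in (0, 1):
            raise ManifestError(f"subject {sid}: non-binary label {row.label}")
        if sid in labels and labels[sid] != label:
            raise ManifestError(f"subject {sid}: conflicting labels")
        labels[sid] = label
        volumes.append(VolumeWithMask(
            intensities=intensities, mask=mask, subject_id=sid,
            sequence_tag=str(row.sequence), tissue_tag=str(row.tissue),
        ))
    cov_cols = [c for c in manifest.columns if c.startswith("cov_")]
    covariates = manifest[["subject_id", "label", *cov_cols]].drop_duplicates("subject_id")
    return volumes, labels, covariates.reset_index(drop=True)


# ---------------------------------------------------------------------------
# CSV / JSON artifacts


def write_csv(df: pd.DataFrame, path: str | Path, config_hash: str = "",
              index: bool = True) -> None:
    """CSV with a leading `# config_hash:` comment, written atomically."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, index=index)
    tmp.replace(path)


def read_csv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def write_feature_table(table: FeatureTable, path: str | Path,
                        config_hash: str = "") -> None:
    """Feature table as CSV plus a JSON sidecar with labels and provenance."""
    path = Path(path)
    df = table.data.copy()
    df.index.name = "subject_id"
    write_csv(df, path, config_hash)
    sidecar = {
        "config_hash": config_hash,
        "labels": {str(k): int(v) for k, v in table.labels.items()},
        "provenance": table.provenance,
    }
    with open(path.with_suffix(".meta.json"), "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)


def read_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    data = read_csv(path, index_col="subject_id")
    with open(path.with_suffix(".meta.json")) as fh:
        sidecar = json.load(fh)
    labels = pd.Series({k: int(v) for k, v in sidecar["labels"].items()},
                       name="label").loc[data.index]
    return FeatureTable(data=data, labels=labels,
                        provenance=sidecar.get("provenance", {}))


def write_json(obj: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
    tmp.replace(path)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
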