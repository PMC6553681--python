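# texrad

Texture radiomics for masked 3D brain-image regions: per-slice extraction of
114 texture descriptors, median aggregation to 3D, univariate screening with
family-wise error control, and repeated cross-validated classifier evaluation
with fold-internal filter feature selection — exercised end-to-end on
synthetic phantom cohorts.

## What it computes

For each (subject, sequence, tissue) volume + binary ROI mask, every 2D slice
with enough in-mask pixels yields 114 named descriptors; the 3D descriptor is
the per-feature median over slices:

| family | count | content |
|--------|------:|---------|
| GLCM   | 13 | Haralick statistics of the symmetrised co-occurrence matrix (Ng=32, d=1), averaged over 0/45/90/135 degrees |
| GLRLM  | 11 | run-length statistics, same quantization and direction averaging |
| LBP    | 40 | 36-bin rotation-invariant local-binary-pattern histogram (8 neighbours, radius 1, min-rotation canonicalisation) + median/variance/skewness/kurtosis of the code map |
| WSF    | 26 | mean/SD of the in-mask intensities and of all subbands of a 3-level orthonormal Haar decomposition |
| WCF    | 24 | 6 Haralick statistics of each quantized level-1 Haar subband |

Downstream: feature-table assembly and cleaning (invalid and
near-zero-variance column removal, leakage-safe standardization), per-feature
Mann-Whitney U screening with Holm step-down correction, and 10x-repeated
stratified 5-fold cross-validation of a linear SVM (C grid) and a random
forest (mtry grid, 250 trees) with optional fold-internal p-value or
maximal-information-coefficient (MIC) feature ranking, reported as mean AUC
+/- SD over the 50 iterations.

A `synthetic` module generates seeded two-class phantom cohorts (Gaussian
random fields whose smoothing scale and local contrast differ by a
controllable effect size, with blob/shell/scatter masks) so the entire
pipeline is testable without any image download.

## CLI

Stages chain through a YAML config and a run directory; each stage reads the
previous stage's files, so everything is resumable and deterministic under a
fixed seed.

```sh
texrad simulate --config config.yaml   # phantom cohort -> NIfTI + manifest.csv
texrad extract  --config config.yaml   # 114 descriptors per volume -> features.csv
texrad clean    --config config.yaml   # invalid/NZV removal -> features_clean.csv
texrad screen   --config config.yaml   # U tests + Holm -> screen_summary.csv
texrad evaluate --config config.yaml   # repeated CV over the grids -> cv_result.json
texrad sweep    --config config.yaml   # AUC vs top-k profile -> sweep_profile.csv
texrad report   --config config.yaml   # summary tables from stage outputs
```

Minimal config:

```yaml
seed: 1
out_dir: runs/demo
phantom:
  spec: {volume_shape: [24, 24, 10], mask_fraction: 0.25, effect_size: 2.0}
  n_per_class: 10
cv: {k: 5, repeats: 10}
ranking: {method: mic}
```

Unknown keys are rejected; every CSV artifact records the config hash in a
leading comment line, and `run.log` records hash, seed and versions.

## Conventions worth knowing

- Quantization uses the in-mask min-max of the whole volume by default so
  all slices share one grey scale (`range_policy: slice` reverts to
  per-slice ranges); the maximum maps to level Ng, constant regions to 1.
- Features that are undefined on degenerate inputs (single-cell GLCM,
  empty LBP neighbourhood, too-small wavelet crop) come back NaN with a
  per-feature validity flag — never as an exception — and are dropped by
  the cleaning stage.
- Standardization uses the sample SD (n-1); entropies use natural logs;
  LBP skewness/kurtosis are moment-based, kurtosis non-excess.
- Cross-validation standardizes and ranks features inside each training
  fold by default (`standardize_mode="global"` reproduces
  standardize-then-split behaviour when explicitly requested).
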