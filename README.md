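# radagree

Radiomic feature extraction from paired CT/MRI tumor volumes and
ICC-based feature-agreement analysis, with a synthetic phantom cohort
generator standing in for patient data.

The package implements, end to end and without calling any existing
radiomics software:

- **image_model** — `ImageVolume` / `ROIMask` / `PatientRecord` domain types
  with NIfTI-1 reading/writing and geometric consistency checks
  (axis-aligned orientations only).
- **preprocess** — three voxel-resampling strategies (`original`,
  `internal`, `external`; cubic B-spline for images, nearest neighbor for
  masks), MRI histogram-matching normalization against a healthy-reference
  volume, and fixed-bin-number discretization (64 bins by default), applied
  in that order.
- **texture_matrices** — 3-D GLCM (13 Chebyshev-1 offsets), GLRLM,
  GLSZM (26-connected zones) and NGTDM builders, with merge/average
  aggregation variants.
- **features** — the 66 named features (4 shape, 16 histogram, 18 GLCM,
  11 GLRLM, 12 GLZLM, 5 NGTDM) computed under a named *extraction dialect*.
  The two built-in dialects A and B bundle implementation choices that
  legitimately differ between extraction programs (matrix aggregation,
  mesh vs voxel-face surface area, resampling grid anchor, NGTDM edge
  rule); all entropies are log2, variance/MAD use population
  normalization, kurtosis is excess (Fisher) by default.
- **agreement** — two-way mixed-effects, absolute-agreement,
  single-measurement ICC with poor/moderate/good/excellent banding
  (<0.5 / 0.5–0.75 / 0.75–0.9 / ≥0.9), per-feature cohort comparisons
  (dialect A vs B at fixed modality; CT vs MRI at fixed dialect) and
  band-percentage / stable-feature reporting.
- **synthetic** — paired CT-like/MRI-like phantom cohorts with shared
  tumor geometry (randomized perturbed ellipsoids), Gaussian-random-field
  texture with a tunable cross-modality correlation `rho`, modality noise
  and an MRI bias field, plus tiny fixed phantoms for oracle tests.
- **cli / pipeline** — the experiment driver over the full
  (patient × modality × dialect × resampling arm) grid.

## CLI

```sh
radagree config init -o config.yaml      # write defaults (desk-scale cohort)
radagree simulate -c config.yaml -o cohort/ --seed 7
radagree extract  -c config.yaml -i cohort/ -o features.csv
radagree agree    -c config.yaml -i features.csv -o report/
radagree report   -i report/agreement_per_feature.json
```

`simulate` writes per-patient NIfTI volumes/masks and a `truth.csv`;
`extract` writes the tidy feature table (one row per patient, modality,
dialect, arm, feature); `agree` writes `agreement_bands.csv` (one row per
comparison arm with one-decimal band percentages), a per-feature JSON
summary and a plain-text table, each carrying a provenance header
(version, seed, config hash). Default grids are reduced (~64³ CT) so the
full grid runs on one CPU in minutes; `simulate --full-size` restores
clinical extents.

## Notes

- Masks are stored unsigned 8-bit; any nonzero voxel is foreground.
- Degenerate features (constant ROI, single voxel, …) are NaN-valued and
  flagged rather than dropped, so cohort tables stay rectangular; in
  cohort ICCs the affected patients are dropped per feature (at least 3
  subjects required).
- Negative ICCs are reported as computed and banded "poor" (no clamping).
  An F statistic and p-value accompany each ICC but never affect banding.
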