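"""Paired CT-like / MRI-like phantom cohorts with shared tumor geometry,
modality-specific intensity and noise models, and a tunable cross-modality
texture correlation, plus the tiny fixed phantoms used by the oracle tests.

Intensity models (arbitrary but documented units):

* CT: lung background at -800 HU, a thin soft-tissue shell at 40 HU around
  the tumor, tumor interior at 60 HU plus an amplitude-scaled Gaussian
  random texture field, plus i.i.d. Gaussian noise.
* MRI: the same tissue map pushed through an affine intensity rescale,
  multiplied by a smooth bias field, with its own texture field
  ``T_MRI = rho * T_shared + sqrt(1 - rho^2) * T_indep`` where ``T_shared``
  is the CT texture field resampled onto the MRI grid (re-standardized so
  the mixture has unit variance), plus Gaussian noise.

Both grids are centered on the world origin so the tumor lands in the same
physical place on each modality's grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_model import (
    ImageVolume,
    Modality,
    PatientRecord,
    ROIMask,
    write_mask,
    write_volume,
)

__all__ = [
    "CohortSpec",
    "TumorShape",
    "Phantom",
    "make_tumor_shape",
    "render_patient",
    "generate_cohort",
    "reference_volume",
    "fixture_phantoms",
    "matched_spec",
]

# CT tissue values (HU-like)
LUNG_HU = -800.0
SHELL_HU = 40.0
TUMOR_HU = 60.0


@dataclass
class CohortSpec:
    """Parameters of one synthetic paired cohort.

    Defaults follow clinical-scale geometry (tumors 20-150 mm on a grid
    large enough to hold them); :func:`CohortSpec.desk` shrinks grid and
    tumors so the full pipeline runs at desk scale.
    """

    n_patients: int = 35
    seed: int = 0
    tumor_diameter_range: tuple[float, float] = (20.0, 150.0)
    ct_spacing: tuple[float, float, float] = (0.7, 0.7, 2.0)
    mri_spacing: tuple[float, float, float] = (1.4, 1.4, 2.5)
    ct_shape: tuple[int, int, int] = (256, 256, 96)
    mri_shape: tuple[int, int, int] = (128, 128, 80)
    texture_correlation: float = 1.0
    texture_amplitude: float = 20.0
    texture_length_scale: float = 4.0  # mm
    ct_noise_sd: float = 5.0
    mri_noise_sd: float = 15.0
    mri_bias_amplitude: float = 0.2
    mri_intensity_scale: float = 0.3
    mri_intensity_offset: float = 400.0
    shape_perturbation: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.texture_correlation <= 1.0):
            raise ValueError(
                f"texture_correlation must be in [0, 1], got {self.texture_correlation}"
            )
        for name in ("ct_noise_sd", "mri_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        lo, hi = self.tumor_diameter_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid tumor_diameter_range {self.tumor_diameter_range}")
        fov = self.min_fov()
        if hi >= fov:
            raise ValueError(
                f"tumor_diameter_range upper bound {hi} mm does not fit the "
                f"field of view ({fov:.1f} mm); enlarge the grid or shrink tumors"
            )

    def min_fov(self) -> float:
        fovs = [
            min(np.asarray(shape) * np.asarray(spacing))
            for shape, spacing in (
                (self.ct_shape, self.ct_spacing),
                (self.mri_shape, self.mri_spacing),
            )
        ]
        return float(min(fovs))

    @classmethod
    def desk(cls, **overrides) -> "CohortSpec":
        """Reduced-size configuration (~64^3 CT grid) for desk-scale runs."""
        defaults = dict(
            ct_shape=(64, 64, 32),
            mri_shape=(40, 40, 28),
            tumor_diameter_range=(16.0, 30.0),
        )
        defaults.update(overrides)
        return cls(**defaults)


def matched_spec(rho: float, seed: int = 0, n_patients: int = 35, **overrides) -> CohortSpec:
    """Desk-scale spec where the MRI arm shares the CT grid and intensity
    model, so the modalities differ only through texture coupling (rho),
    bias and noise.  Used to give the agreement analysis a known ground
    truth to recover."""
    defaults = dict(
        texture_correlation=rho,
        seed=seed,
        n_patients=n_patients,
        mri_spacing=(0.7, 0.7, 2.0),
        mri_shape=(64, 64, 32),
        mri_intensity_scale=1.0,
        mri_intensity_offset=0.0,
        mri_bias_amplitude=0.0,
        ct_noise_sd=2.0,
        mri_noise_sd=2.0,
    )
    defaults.update(overrides)
    return CohortSpec.desk(**defaults)


@dataclass
class TumorShape:
    """Randomized blob: an ellipsoid with lognormal semi-axes perturbed by
    smooth low-frequency radial noise, as an implicit function of world
    coordinates (positive inside).  The boundary never exceeds
    ``diameter / 2`` from the center."""

    semi_axes: np.ndarray
    diameter: float
    perturbation: float
    wave_vectors: np.ndarray  # (m, 3)
    wave_phases: np.ndarray  # (m,)
    wave_coeffs: np.ndarray  # (m,)

    def _radial_noise(self, units: np.ndarray) -> np.ndarray:
        """Smooth direction-dependent perturbation in [-1, 1]."""
        phase = units @ self.wave_vectors.T + self.wave_phases
        raw = np.cos(phase) @ self.wave_coeffs
        norm = np.abs(self.wave_coeffs).sum()
        return raw / norm if norm > 0 else np.zeros(units.shape[:-1])

    def implicit(self, points: np.ndarray) -> np.ndarray:
        """Evaluate at world points (..., 3); >= 0 inside the tumor."""
        pts = np.asarray(points, dtype=np.float64)
        rho = np.sqrt(((pts / self.semi_axes) ** 2).sum(axis=-1))
        r = np.linalg.norm(pts, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            units = np.where(r[..., None] > 0, pts / np.maximum(r, 1e-12)[..., None], 0.0)
        return 1.0 + self.perturbation * self._radial_noise(units) - rho

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.implicit(points) >= 0

    def volume_by_sampling(self, step: float = 0.5) -> float:
        """Dense-sampling estimate of the enclosed volume (mm^3)."""
        r = self.diameter / 2.0
        axes = [np.arange(-r, r + step, step) for _ in range(3)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        return float(self.contains(grid).sum()) * step**3


def make_tumor_shape(seed: int, diameter: float, perturbation: float = 0.1) -> TumorShape:
    """Deterministic randomized tumor shape of the given diameter (mm)."""
    rng = np.random.default_rng(seed)
    axes = np.exp(rng.normal(0.0, 0.15, size=3))
    # scale so the maximal possible radius (largest axis * (1 + perturbation))
    # equals diameter / 2: the implicit function is negative outside that bound
    axes *= (diameter / 2.0) / (axes.max() * (1.0 + perturbation))
    m = 6
    wave_vectors = rng.uniform(-2.0, 2.0, size=(m, 3))
    wave_phases = rng.uniform(0.0, 2.0 * np.pi, size=m)
    wave_coeffs = rng.normal(0.0, 1.0, size=m)
    return TumorShape(
        semi_axes=axes,
        diameter=float(diameter),
        perturbation=float(perturbation),
        wave_vectors=wave_vectors,
        wave_phases=wave_phases,
        wave_coeffs=wave_coeffs,
    )


@dataclass
class Phantom:
    record: PatientRecord
    truth: dict[str, float]


def _grid_world_axes(shape, spacing) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-axis world coordinates of a grid centered on the world origin."""
    shape = np.asarray(shape)
    spacing = np.asarray(spacing, dtype=float)
    origin = -(shape - 1) * spacing / 2.0
    axes = [origin[d] + np.arange(shape[d]) * spacing[d] for d in range(3)]
    return axes, origin


def _eval_on_grid(shape, spacing, func) -> tuple[np.ndarray, np.ndarray]:
    axes, origin = _grid_world_axes(shape, spacing)
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    return func(pts), origin


def _gaussian_field(rng: np.random.Generator, shape, spacing, length_scale: float) -> np.ndarray:
    """Unit-variance Gaussian random field: white noise smoothed to the
    requested physical length scale."""
    white = rng.standard_normal(tuple(shape))
    sigma = np.asarray(length_scale, dtype=float) / np.asarray(spacing, dtype=float)
    fieldv = ndimage.gaussian_filter(white, sigma=sigma, mode="reflect")
    sd = fieldv.std()
    return fieldv / sd if sd > 0 else fieldv


def _resample_field(
    src: np.ndarray, src_spacing, src_origin, dst_shape, dst_spacing, dst_origin
) -> np.ndarray:
    """Linear resampling of a scalar field between two world-aligned grids."""
    idx = np.indices(tuple(dst_shape), dtype=np.float64)
    coords = np.empty_like(idx)
    for d in range(3):
        world = dst_origin[d] + idx[d] * dst_spacing[d]
        coords[d] = (world - src_origin[d]) / src_spacing[d]
    return ndimage.map_coordinates(src, coords, order=1, mode="nearest")


def _child_rngs(seed: int, patient_index: int) -> dict[str, np.random.Generator]:
    """Per-patient, per-purpose generators.

    Child seeds derive from ``SeedSequence([seed, patient_index, stream])``
    so patients are independent and runs reproducible.
    """
    streams = ("shape", "ct", "mri", "bias")
    return {
        name: np.random.default_rng(np.random.SeedSequence([seed, patient_index, i]))
        for i, name in enumerate(streams)
    }


def render_patient(spec: CohortSpec, patient_index: int) -> Phantom:
    """Render one paired CT/MRI phantom with shared tumor geometry."""
    rngs = _child_rngs(spec.seed, patient_index)
    lo, hi = spec.tumor_diameter_range
    diameter = float(rngs["shape"].uniform(lo, hi))
    shape_seed = int(rngs["shape"].integers(0, 2**31 - 1))
    tumor = make_tumor_shape(shape_seed, diameter, spec.shape_perturbation)

    fov = spec.min_fov()
    if diameter >= fov:
        raise ValueError(f"tumor diameter {diameter:.1f} mm exceeds field of view {fov:.1f} mm")

    # CT
    ct_spacing = np.asarray(spec.ct_spacing, dtype=float)
    ct_mask, ct_origin = _eval_on_grid(spec.ct_shape, ct_spacing, tumor.contains)
    t_ct = _gaussian_field(rngs["ct"], spec.ct_shape, ct_spacing, spec.texture_length_scale)
    shell = ndimage.binary_dilation(ct_mask, iterations=3) & ~ct_mask
    ct_data = np.full(tuple(spec.ct_shape), LUNG_HU)
    ct_data[shell] = SHELL_HU
    ct_data[ct_mask] = TUMOR_HU + spec.texture_amplitude * t_ct[ct_mask]
    ct_data += rngs["ct"].normal(0.0, spec.ct_noise_sd, size=ct_data.shape)

    # MRI
    mri_spacing = np.asarray(spec.mri_spacing, dtype=float)
    mri_mask, mri_origin = _eval_on_grid(spec.mri_shape, mri_spacing, tumor.contains)
    rho = spec.texture_correlation
    t_shared = _resample_field(
        t_ct, ct_spacing, ct_origin, spec.mri_shape, mri_spacing, mri_origin
    )
    sd = t_shared.std()
    if sd > 0:
        t_shared = t_shared / sd
    t_indep = _gaussian_field(
        rngs["mri"], spec.mri_shape, mri_spacing, spec.texture_length_scale
    )
    t_mri = rho * t_shared + np.sqrt(1.0 - rho**2) * t_indep

    mri_shell = ndimage.binary_dilation(mri_mask, iterations=2) & ~mri_mask
    tissue = np.full(tuple(spec.mri_shape), LUNG_HU)
    tissue[mri_shell] = SHELL_HU
    tissue[mri_mask] = TUMOR_HU + spec.texture_amplitude * t_mri[mri_mask]
    mri_data = spec.mri_intensity_scale * tissue + spec.mri_intensity_offset
    if spec.mri_bias_amplitude > 0:
        bias = _gaussian_field(rngs["bias"], spec.mri_shape, mri_spacing, 20.0)
        mri_data = mri_data * (1.0 + spec.mri_bias_amplitude * bias)
    mri_data += rngs["mri"].normal(0.0, spec.mri_noise_sd, size=mri_data.shape)

    if not ct_mask.any() or not mri_mask.any():
        raise ValueError("tumor produced an empty mask")

    record = PatientRecord(
        patient_id=f"P{patient_index:03d}",
        ct=(
            ImageVolume(ct_data, ct_spacing, ct_origin, Modality.CT),
            ROIMask(ct_mask, ct_spacing, ct_origin),
        ),
        mri=(
            ImageVolume(mri_data, mri_spacing, mri_origin, Modality.MRI),
            ROIMask(mri_mask, mri_spacing, mri_origin),
        ),
    )
    sampling_step = max(0.5, diameter / 80.0)
    truth = {
        "patient_id": record.patient_id,
        "diameter_mm": diameter,
        "volume_mm3": tumor.volume_by_sampling(step=sampling_step),
        "texture_correlation": rho,
        "seed": spec.seed,
        "shape_seed": shape_seed,
    }
    return Phantom(record=record, truth=truth)


def generate_cohort(
    spec: CohortSpec, out_dir: str | Path | None = None
) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Render the whole cohort; optionally write NIfTI files + truth CSV."""
    phantoms = [render_patient(spec, i) for i in range(spec.n_patients)]
    records = [p.record for p in phantoms]
    truth = pd.DataFrame([p.truth for p in phantoms])
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec in records:
            for modality in (Modality.CT, Modality.MRI):
                vol, mask = rec.pair(modality)
                stem = f"{rec.patient_id}_{modality.value}"
                write_volume(vol, out_dir / f"{stem}_image.nii")
                write_mask(mask, out_dir / f"{stem}_mask.nii")
        truth.to_csv(out_dir / "truth.csv", index=False)
    return records, truth


def reference_volume(spec: CohortSpec, seed_offset: int = 10_000) -> ImageVolume:
    """Healthy-subject surrogate MRI (no tumor) for histogram matching."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, seed_offset]))
    spacing = np.asarray(spec.mri_spacing, dtype=float)
    _, origin = _grid_world_axes(spec.mri_shape, spacing)
    t = _gaussian_field(rng, spec.mri_shape, spacing, spec.texture_length_scale)
    tissue = np.full(tuple(spec.mri_shape), LUNG_HU) + spec.texture_amplitude * t
    data = spec.mri_intensity_scale * tissue + spec.mri_intensity_offset
    data += rng.normal(0.0, spec.mri_noise_sd, size=data.shape)
    return ImageVolume(data, spacing, origin, Modality.MRI)


def fixture_phantoms() -> dict[str, tuple[ImageVolume, ROIMask]]:
    """Fixed tiny phantoms with hand-checkable feature values.

    * ``cube``: 10x10x10 solid mask (1 mm spacing) with an intensity ramp.
    * ``line_run``: 1x1x5 constant ROI (single run of length 5).
    * ``const3``: 3x3x3 constant ROI.
    * ``checkerboard``: 4x4x4 two-level checkerboard alternating along all axes.
    """
    out: dict[str, tuple[ImageVolume, ROIMask]] = {}

    cube_grid = np.zeros((12, 12, 12))
    cube_mask = np.zeros((12, 12, 12), dtype=bool)
    cube_mask[1:11, 1:11, 1:11] = True
    i, j, k = np.indices((12, 12, 12))
    cube_grid[:] = i + 2.0 * j + 3.0 * k
    out["cube"] = (
        ImageVolume(cube_grid, (1, 1, 1), (0, 0, 0), Modality.CT),
        ROIMask(cube_mask, (1, 1, 1), (0, 0, 0)),
    )

    line = np.full((1, 1, 5), 7.0)
    out["line_run"] = (
        ImageVolume(line, (1, 1, 1), (0, 0, 0), Modality.CT),
        ROIMask(np.ones((1, 1, 5)), (1, 1, 1), (0, 0, 0)),
    )

    const = np.full((3, 3, 3), 5.0)
    out["const3"] = (
        ImageVolume(const, (1, 1, 1), (0, 0, 0), Modality.CT),
        ROIMask(np.ones((3, 3, 3)), (1, 1, 1), (0, 0, 0)),
    )

    i, j, k = np.indices((4, 4, 4))
    board = ((i + j + k) % 2).astype(float) * 10.0 + 5.0
    out["checkerboard"] = (
        ImageVolume(board, (1, 1, 1), (0, 0, 0), Modality.CT),
        ROIMask(np.ones((4, 4, 4)), (1, 1, 1), (0, 0, 0)),
    )
    return out
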