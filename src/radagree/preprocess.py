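"""Resampling, MRI histogram-matching normalization, and fixed-bin-number
intensity discretization, applied in the order resample -> normalize ->
discretize.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage

from .image_model import ImageVolume, Modality, ROIMask

__all__ = [
    "Strategy",
    "GridAnchor",
    "ResamplingSpec",
    "NormalizationSpec",
    "DiscretizedROI",
    "DEFAULT_TARGET_SPACING",
    "DEFAULT_N_BINS",
    "resample",
    "resample_volume",
    "histogram_match",
    "discretize",
    "preprocess_pair",
    "PreprocessedModality",
]

DEFAULT_N_BINS = 64

#: Default isotropic target spacings (mm) per modality.
DEFAULT_TARGET_SPACING = {
    Modality.CT: (1.0, 1.0, 1.0),
    Modality.MRI: (1.4, 1.4, 1.4),
}


class Strategy(str, Enum):
    ORIGINAL = "original"
    INTERNAL = "internal"
    EXTERNAL = "external"


class GridAnchor(str, Enum):
    """Where the resampled grid is anchored relative to the input grid.

    ``corner``: output voxel 0 coincides with input voxel 0 (origin
    preserved).  ``center``: the output grid is shifted so that grid centers
    coincide.  The two conventions are one concrete way real extraction
    programs disagree about resampling.
    """

    CORNER = "corner"
    CENTER = "center"


_INTERP_ORDER = {"bspline3": 3, "linear": 1, "nearest": 0}


@dataclass
class ResamplingSpec:
    strategy: Strategy = Strategy.ORIGINAL
    target_spacing: tuple[float, float, float] | None = None
    image_interpolator: str = "bspline3"
    mask_interpolator: str = "nearest"

    def __post_init__(self) -> None:
        self.strategy = Strategy(self.strategy)
        if self.image_interpolator not in _INTERP_ORDER:
            raise ValueError(f"unknown image_interpolator {self.image_interpolator!r}")
        if self.mask_interpolator != "nearest":
            raise ValueError("mask_interpolator must be 'nearest'")
        if self.target_spacing is not None:
            ts = np.asarray(self.target_spacing, dtype=float)
            if ts.shape != (3,) or np.any(ts <= 0):
                raise ValueError("target_spacing components must be > 0")
            self.target_spacing = tuple(ts)

    def resolved_target(self, modality: Modality) -> np.ndarray:
        if self.target_spacing is not None:
            return np.asarray(self.target_spacing, dtype=float)
        return np.asarray(DEFAULT_TARGET_SPACING[Modality(modality)], dtype=float)


@dataclass
class NormalizationSpec:
    """Histogram-matching normalization against a healthy-reference volume."""

    enabled: bool = True
    reference: ImageVolume | None = None
    histogram_levels: int = 128
    match_points: int = 64
    exclude_background: bool = True

    def __post_init__(self) -> None:
        if not (2 <= self.match_points < self.histogram_levels):
            raise ValueError(
                "match_points must satisfy 2 <= match_points < histogram_levels "
                f"(got {self.match_points}, {self.histogram_levels})"
            )


@dataclass
class DiscretizedROI:
    """ROI voxels mapped to integer gray bins 1..n_bins (0 outside ROI)."""

    bins: np.ndarray
    n_bins: int
    roi_min: float
    roi_max: float
    voxel_count: int
    degenerate: bool = False
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))

    @property
    def roi(self) -> np.ndarray:
        return self.bins > 0


def _output_size(in_shape, in_spacing, target) -> np.ndarray:
    # size_d = ceil(in_size_d * in_spacing_d / target_d); guard float fuzz so
    # that resampling to the native spacing reproduces the native size
    exact = np.asarray(in_shape) * np.asarray(in_spacing) / np.asarray(target)
    return np.maximum(np.ceil(exact - 1e-9).astype(int), 1)


def _resample_array(
    data: np.ndarray,
    in_spacing: np.ndarray,
    target: np.ndarray,
    order: int,
    anchor: GridAnchor,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample one array; returns (resampled, world shift of the new origin)."""
    in_shape = np.asarray(data.shape)
    out_shape = _output_size(in_shape, in_spacing, target)
    if anchor is GridAnchor.CORNER:
        shift = np.zeros(3)
    else:
        shift = ((in_shape - 1) * in_spacing - (out_shape - 1) * target) / 2.0
    idx = np.indices(out_shape, dtype=np.float64)
    coords = np.empty_like(idx)
    for d in range(3):
        coords[d] = (idx[d] * target[d] + shift[d]) / in_spacing[d]
    out = ndimage.map_coordinates(
        np.asarray(data, dtype=np.float64), coords, order=order, mode="nearest"
    )
    return out, shift


def resample_volume(
    vol: ImageVolume, spec: ResamplingSpec, anchor: GridAnchor = GridAnchor.CORNER
) -> ImageVolume:
    """Resample a bare volume (no mask) onto the spec's target grid."""
    if spec.strategy is Strategy.ORIGINAL:
        return vol
    target = spec.resolved_target(vol.modality)
    out, shift = _resample_array(
        vol.data, vol.spacing, target, _INTERP_ORDER[spec.image_interpolator], anchor
    )
    return ImageVolume(
        data=out, spacing=target, origin=vol.origin + shift, modality=vol.modality
    )


def resample(
    vol: ImageVolume,
    mask: ROIMask,
    spec: ResamplingSpec,
    anchor: GridAnchor = GridAnchor.CORNER,
) -> tuple[ImageVolume, ROIMask]:
    """Resample a volume/mask pair onto the target spacing.

    The image is interpolated with a cubic B-spline (by default), the mask
    with nearest neighbor; out-of-grid samples clamp to the nearest edge
    value.  ``strategy='original'`` returns the inputs unchanged.
    """
    mask.check_against(vol)
    if spec.strategy is Strategy.ORIGINAL:
        return vol, mask
    out_vol = resample_volume(vol, spec, anchor)
    target = spec.resolved_target(vol.modality)
    out_mask_data, shift = _resample_array(
        mask.data.astype(np.float64), mask.spacing, target, 0, anchor
    )
    out_mask = ROIMask(
        data=out_mask_data > 0.5, spacing=target, origin=mask.origin + shift
    )
    if out_mask.voxel_count == 0:
        raise ValueError("ROI vanished under resampling")
    return out_vol, out_mask


def _piecewise_linear(x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """Monotone piecewise-linear map through (xp, fp), extended linearly
    beyond the first/last knot with the adjacent segment slope."""
    xp, idx = np.unique(xp, return_index=True)
    fp = fp[idx]
    if xp.size == 1:
        return np.full_like(np.asarray(x, dtype=float), fp[0])
    y = np.interp(x, xp, fp)
    lo_slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
    hi_slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
    below = x < xp[0]
    above = x > xp[-1]
    y = np.where(below, fp[0] + (x - xp[0]) * lo_slope, y)
    y = np.where(above, fp[-1] + (x - xp[-1]) * hi_slope, y)
    return y


def histogram_match(vol: ImageVolume, spec: NormalizationSpec) -> ImageVolume:
    """Map *vol* intensities so their quantiles align with the reference's.

    ``match_points`` quantiles of source and reference are paired (computed
    over voxels above the mean-intensity background threshold when
    ``exclude_background``) and joined by a monotone piecewise-linear map.
    """
    if not spec.enabled:
        return vol
    if spec.reference is None:
        raise ValueError("histogram matching requires a reference volume")
    src = vol.data.ravel()
    ref = spec.reference.data.ravel()
    if spec.exclude_background:
        src_sel = src[src > src.mean()]
        ref_sel = ref[ref > ref.mean()]
    else:
        src_sel, ref_sel = src, ref
    if ref_sel.size == 0 or np.ptp(ref_sel) == 0:
        raise ValueError("reference has zero intensity spread")
    if src_sel.size == 0 or np.ptp(src_sel) == 0:
        raise ValueError("source has zero intensity spread above background")
    levels = np.linspace(0.0, 1.0, spec.match_points)
    src_q = np.quantile(src_sel, levels)
    ref_q = np.quantile(ref_sel, levels)
    mapped = _piecewise_linear(vol.data.astype(np.float64), src_q, ref_q)
    return ImageVolume(
        data=mapped.reshape(vol.shape),
        spacing=vol.spacing,
        origin=vol.origin,
        modality=vol.modality,
    )


def discretize(vol: ImageVolume, mask: ROIMask, n_bins: int = DEFAULT_N_BINS) -> DiscretizedROI:
    """Fixed-bin-number discretization of in-ROI intensities.

    ``bin(x) = min(floor(n_bins * (x - roi_min)/(roi_max - roi_min)) + 1, n_bins)``;
    a constant ROI maps everything to bin 1 and is flagged degenerate.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    mask.check_against(vol)
    roi = mask.data
    count = int(roi.sum())
    if count == 0:
        raise ValueError("mask is empty")
    vals = vol.data[roi]
    roi_min = float(vals.min())
    roi_max = float(vals.max())
    bins = np.zeros(vol.shape, dtype=np.int32)
    if roi_max > roi_min:
        scaled = np.floor(n_bins * (vals - roi_min) / (roi_max - roi_min)).astype(np.int64) + 1
        bins[roi] = np.minimum(scaled, n_bins)
        degenerate = False
    else:
        bins[roi] = 1
        degenerate = True
    return DiscretizedROI(
        bins=bins,
        n_bins=n_bins,
        roi_min=roi_min,
        roi_max=roi_max,
        voxel_count=count,
        degenerate=degenerate,
        spacing=np.asarray(vol.spacing, dtype=float),
    )


@dataclass
class PreprocessedModality:
    volume: ImageVolume
    mask: ROIMask
    discretized: DiscretizedROI


def preprocess_pair(
    record,
    ct_spec: ResamplingSpec,
    mri_spec: ResamplingSpec,
    norm: NormalizationSpec | None = None,
    n_bins: int = DEFAULT_N_BINS,
    anchor: GridAnchor = GridAnchor.CORNER,
) -> dict[Modality, PreprocessedModality]:
    """Run resample -> (MRI) histogram_match -> discretize for one patient.

    All intermediates are returned for inspection.  The normalization
    reference, when present, is resampled to the MRI working spacing before
    quantiles are taken.
    """
    out: dict[Modality, PreprocessedModality] = {}
    for modality, spec in ((Modality.CT, ct_spec), (Modality.MRI, mri_spec)):
        vol, mask = record.pair(modality)
        vol, mask = resample(vol, mask, spec, anchor)
        if modality is Modality.MRI and norm is not None and norm.enabled:
            ref = norm.reference
            if ref is not None and spec.strategy is not Strategy.ORIGINAL:
                ref = resample_volume(ref, spec, anchor)
            vol = histogram_match(
                vol,
                NormalizationSpec(
                    enabled=True,
                    reference=ref,
                    histogram_levels=norm.histogram_levels,
                    match_points=norm.match_points,
                    exclude_background=norm.exclude_background,
                ),
            )
        out[modality] = PreprocessedModality(vol, mask, discretize(vol, mask, n_bins))
    return out
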