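"""The 66 named radiomic features (4 shape, 16 histogram, 18 GLCM, 11 GLRLM,
12 GLZLM, 5 NGTDM) computed from a preprocessed volume/mask/discretization
triple under a named extraction dialect.

Feature keys are category-prefixed (``GLCM_Energy`` vs ``HISTOGRAM_Energy``)
because several short names repeat across categories.  Formulas follow the
IBSI reference definitions; all entropies use log base 2.  Degenerate inputs
(constant ROI, single voxel) yield NaN values carried with flags rather than
exceptions, so cohort tables stay rectangular.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage.measure import marching_cubes, mesh_surface_area

from .image_model import ImageVolume, ROIMask
from .preprocess import DiscretizedROI
from .texture_matrices import (
    Aggregation,
    GLCMatrix,
    GLRLMatrix,
    GLSZMatrix,
    NGTDMatrix,
    NGTDMEdgeRule,
    glcm,
    glrlm,
    glszm,
    ngtdm,
)

__all__ = [
    "Category",
    "SurfaceAlgorithm",
    "ExtractionDialect",
    "DIALECT_A",
    "DIALECT_B",
    "BUILTIN_DIALECTS",
    "FeatureVector",
    "FEATURE_NAMES",
    "CATEGORY_COUNTS",
    "shape_features",
    "histogram_features",
    "glcm_features",
    "glrlm_features",
    "glzlm_features",
    "ngtdm_features",
    "extract",
]

#: Cap applied to NGTDM Coarseness when sum(p_i * s_i) == 0.
COARSENESS_CAP = 1e6


class Category(str, Enum):
    SHAPE = "SHAPE"
    HISTOGRAM = "HISTOGRAM"
    GLCM = "GLCM"
    GLRLM = "GLRLM"
    GLZLM = "GLZLM"
    NGTDM = "NGTDM"


class SurfaceAlgorithm(str, Enum):
    MESH = "mesh"
    VOXEL_FACE = "voxel_face"


_SHAPE = ["VoxelVolume", "SurfaceArea", "Sphericity", "Maximum3DDiameter"]
_HISTOGRAM = [
    "Skewness", "Kurtosis", "Entropy", "Energy", "Uniformity",
    "Mean", "Median", "Minimum", "Percentile10", "Percentile90", "Maximum",
    "InterquartileRange", "Range", "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation", "Variance",
]
_GLCM = [
    "Contrast", "Correlation", "Dissimilarity", "Energy", "Entropy",
    "InverseDifference", "Autocorrelation", "JointAverage",
    "ClusterProminence", "ClusterTendency", "ClusterShade",
    "DifferenceVariance", "DifferenceEntropy", "InverseVariance",
    "SumEntropy", "JointVariance", "JointMaximum",
    "NormalizedInverseDifference",
]
_GLRLM = [
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "RunLengthNonUniformity", "RunPercentage", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]
_GLZLM = [
    "SmallZoneEmphasis", "LargeZoneEmphasis", "GrayLevelNonUniformity",
    "ZoneSizeNonUniformity", "ZonePercentage", "GrayLevelVariance",
    "LowGrayLevelZoneEmphasis", "HighGrayLevelZoneEmphasis",
    "SmallZoneLowGrayLevelEmphasis", "SmallZoneHighGrayLevelEmphasis",
    "LargeZoneLowGrayLevelEmphasis", "LargeZoneHighGrayLevelEmphasis",
]
_NGTDM = ["Coarseness", "Complexity", "Busyness", "Strength", "Contrast"]

#: All 66 feature keys in fixed (table) order, category-prefixed.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{cat.value}_{name}"
    for cat, names in (
        (Category.SHAPE, _SHAPE),
        (Category.HISTOGRAM, _HISTOGRAM),
        (Category.GLCM, _GLCM),
        (Category.GLRLM, _GLRLM),
        (Category.GLZLM, _GLZLM),
        (Category.NGTDM, _NGTDM),
    )
    for name in names
)

CATEGORY_COUNTS = {
    Category.SHAPE: 4,
    Category.HISTOGRAM: 16,
    Category.GLCM: 18,
    Category.GLRLM: 11,
    Category.GLZLM: 12,
    Category.NGTDM: 5,
}

assert len(FEATURE_NAMES) == 66


@dataclass(frozen=True)
class ExtractionDialect:
    """A named bundle of implementation choices that legitimately differ
    between extraction programs: matrix aggregation, surface algorithm,
    resampling grid anchor, and the NGTDM edge rule."""

    name: str
    glcm_aggregation: Aggregation = Aggregation.MERGE
    glrlm_aggregation: Aggregation = Aggregation.MERGE
    surface_algorithm: SurfaceAlgorithm = SurfaceAlgorithm.MESH
    grid_anchor: str = "corner"
    ngtdm_edge_rule: NGTDMEdgeRule = NGTDMEdgeRule.INCLUDE


DIALECT_A = ExtractionDialect(
    name="A",
    glcm_aggregation=Aggregation.MERGE,
    glrlm_aggregation=Aggregation.MERGE,
    surface_algorithm=SurfaceAlgorithm.MESH,
    grid_anchor="corner",
    ngtdm_edge_rule=NGTDMEdgeRule.INCLUDE,
)
DIALECT_B = ExtractionDialect(
    name="B",
    glcm_aggregation=Aggregation.AVERAGE,
    glrlm_aggregation=Aggregation.AVERAGE,
    surface_algorithm=SurfaceAlgorithm.VOXEL_FACE,
    grid_anchor="center",
    ngtdm_edge_rule=NGTDMEdgeRule.EXCLUDE,
)
BUILTIN_DIALECTS = {"A": DIALECT_A, "B": DIALECT_B}


@dataclass
class FeatureVector:
    """Ordered map of the 66 feature values with categories and flags."""

    values: dict[str, float]
    degenerate_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if tuple(self.values) != FEATURE_NAMES:
            missing = set(FEATURE_NAMES) - set(self.values)
            extra = set(self.values) - set(FEATURE_NAMES)
            raise ValueError(
                f"feature vector must hold exactly the 66 named features in "
                f"order (missing={sorted(missing)}, extra={sorted(extra)})"
            )

    @property
    def categories(self) -> dict[str, Category]:
        return {name: Category(name.split("_", 1)[0]) for name in self.values}

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# shape


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Indices of ROI voxels with a 6-neighbor outside the ROI (or on the
    volume border)."""
    padded = np.pad(mask, 1)
    interior = np.ones_like(padded)
    for d in range(3):
        interior &= np.roll(padded, 1, axis=d) & np.roll(padded, -1, axis=d)
    surf = padded & ~interior
    return np.argwhere(surf[1:-1, 1:-1, 1:-1])


def _voxel_face_area(mask: np.ndarray, spacing: np.ndarray) -> float:
    voxel_vol = float(np.prod(spacing))
    padded = np.pad(mask, 1).astype(np.int8)
    area = 0.0
    for d in range(3):
        exposed = np.abs(np.diff(padded, axis=d)).sum()
        area += exposed * voxel_vol / spacing[d]
    return float(area)


def _mesh_area(mask: np.ndarray, spacing: np.ndarray) -> float:
    padded = np.pad(mask, 1).astype(np.float64)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    return float(mesh_surface_area(verts, faces))


def _max_diameter(mask: np.ndarray, spacing: np.ndarray) -> float:
    pts = _surface_voxels(mask) * spacing
    if pts.shape[0] == 1:
        return 0.0
    if pts.shape[0] > 4:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # coplanar/collinear point sets: brute force below
    return float(pdist(pts).max())


def shape_features(mask: ROIMask, dialect: ExtractionDialect = DIALECT_A) -> dict[str, float]:
    """Voxel volume (mm^3), surface area (mm^2), sphericity, max 3-D
    diameter (mm) between surface-voxel centers."""
    if mask.voxel_count == 0:
        raise ValueError("mask is empty")
    spacing = np.asarray(mask.spacing, dtype=float)
    volume = mask.voxel_count * float(np.prod(spacing))
    if dialect.surface_algorithm is SurfaceAlgorithm.MESH:
        area = _mesh_area(mask.data, spacing)
    else:
        area = _voxel_face_area(mask.data, spacing)
    sphericity = (36.0 * np.pi * volume**2) ** (1.0 / 3.0) / area
    return {
        "SHAPE_VoxelVolume": volume,
        "SHAPE_SurfaceArea": area,
        "SHAPE_Sphericity": float(sphericity),
        "SHAPE_Maximum3DDiameter": _max_diameter(mask.data, spacing),
    }


# ---------------------------------------------------------------------------
# histogram / first order


def histogram_features(
    vol: ImageVolume,
    mask: ROIMask,
    d: DiscretizedROI,
    fisher_kurtosis: bool = True,
) -> tuple[dict[str, float], set[str]]:
    """First-order statistics of raw in-ROI intensities plus Entropy /
    Uniformity from the discretized histogram and Energy = sum(x^2).

    Variance / MAD use population (1/N) normalization; kurtosis is excess
    (Fisher) by default — both are documented conventions, switchable.
    """
    x = vol.data[mask.data].astype(np.float64)
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population
    p10, p25, median, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    band = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(band - band.mean()).mean()) if band.size else float("nan")
    hist = np.bincount(d.bins[d.roi], minlength=d.n_bins + 1)[1:]
    p = hist / hist.sum()
    nz = p[p > 0]
    flags: set[str] = set()
    if var > 0:
        std = np.sqrt(var)
        skew = float(np.mean(((x - mean) / std) ** 3))
        kurt = float(np.mean(((x - mean) / std) ** 4))
        if fisher_kurtosis:
            kurt -= 3.0
    else:
        skew = kurt = float("nan")
        flags |= {"HISTOGRAM_Skewness", "HISTOGRAM_Kurtosis"}
    vals = {
        "HISTOGRAM_Skewness": skew,
        "HISTOGRAM_Kurtosis": kurt,
        "HISTOGRAM_Entropy": float(-(nz * np.log2(nz)).sum()),
        "HISTOGRAM_Energy": float((x**2).sum()),
        "HISTOGRAM_Uniformity": float((p**2).sum()),
        "HISTOGRAM_Mean": mean,
        "HISTOGRAM_Median": float(median),
        "HISTOGRAM_Minimum": float(x.min()),
        "HISTOGRAM_Percentile10": float(p10),
        "HISTOGRAM_Percentile90": float(p90),
        "HISTOGRAM_Maximum": float(x.max()),
        "HISTOGRAM_InterquartileRange": float(p75 - p25),
        "HISTOGRAM_Range": float(x.max() - x.min()),
        "HISTOGRAM_MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "HISTOGRAM_RobustMeanAbsoluteDeviation": rmad,
        "HISTOGRAM_Variance": var,
    }
    return vals, flags


# ---------------------------------------------------------------------------
# GLCM


def _glcm_features_single(p: np.ndarray) -> dict[str, float]:
    n = p.shape[0]
    i = np.arange(1, n + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    pi = p.sum(axis=1)  # marginal (symmetric: both margins equal)
    mu = float((i * pi).sum())
    sigma2 = float(((i - mu) ** 2 * pi).sum())
    absdiff = np.abs(ii - jj)
    # difference distribution p_{|i-j|}, k = 0..n-1
    k = np.arange(n, dtype=np.float64)
    p_diff = np.zeros(n)
    np.add.at(p_diff, absdiff.astype(int).ravel(), p.ravel())
    mu_diff = float((k * p_diff).sum())
    # sum distribution p_{i+j}, s = 2..2n
    s = np.arange(2, 2 * n + 1, dtype=np.float64)
    p_sum = np.zeros(2 * n - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel() - 2, p.ravel())
    nz = p[p > 0]
    nzd = p_diff[p_diff > 0]
    nzs = p_sum[p_sum > 0]
    off = absdiff > 0
    corr = (
        float((ii * jj * p).sum() - mu * mu) / sigma2 if sigma2 > 0 else float("nan")
    )
    return {
        "GLCM_Contrast": float(((ii - jj) ** 2 * p).sum()),
        "GLCM_Correlation": corr,
        "GLCM_Dissimilarity": float((absdiff * p).sum()),
        "GLCM_Energy": float((p**2).sum()),
        "GLCM_Entropy": float(-(nz * np.log2(nz)).sum()),
        "GLCM_InverseDifference": float((p / (1.0 + absdiff)).sum()),
        "GLCM_Autocorrelation": float((ii * jj * p).sum()),
        "GLCM_JointAverage": mu,
        "GLCM_ClusterProminence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "GLCM_ClusterTendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "GLCM_ClusterShade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "GLCM_DifferenceVariance": float(((k - mu_diff) ** 2 * p_diff).sum()),
        "GLCM_DifferenceEntropy": float(-(nzd * np.log2(nzd)).sum()),
        "GLCM_InverseVariance": float((p[off] / (ii - jj)[off] ** 2).sum()),
        "GLCM_SumEntropy": float(-(nzs * np.log2(nzs)).sum()),
        "GLCM_JointVariance": float(((ii - mu) ** 2 * p).sum()),
        "GLCM_JointMaximum": float(p.max()),
        "GLCM_NormalizedInverseDifference": float((p / (1.0 + absdiff / n)).sum()),
    }


def glcm_features(m: GLCMatrix) -> tuple[dict[str, float], set[str]]:
    names = [f"GLCM_{x}" for x in _GLCM]
    if m.degenerate:
        return {k: float("nan") for k in names}, set(names)
    if m.aggregation is Aggregation.MERGE:
        feats = _glcm_features_single(m.merged_p)
    else:
        per_dir = [_glcm_features_single(p) for p in m.directional_p()]
        feats = {
            k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]
        }
    flags = {k for k, v in feats.items() if not np.isfinite(v)}
    return feats, flags


# ---------------------------------------------------------------------------
# GLRLM / GLZLM (shared emphasis-formula core)


def _rl_features(r: np.ndarray, n_vox: int, prefix: str, names: list[str]) -> dict[str, float]:
    ns = r.sum()
    i = np.arange(1, r.shape[0] + 1, dtype=np.float64)[:, None]
    j = np.arange(1, r.shape[1] + 1, dtype=np.float64)[None, :]
    ri = r.sum(axis=1)
    rj = r.sum(axis=0)
    vals = [
        float((r / j**2).sum() / ns),          # short emphasis
        float((r * j**2).sum() / ns),          # long emphasis
        float((ri**2).sum() / ns),             # gray level non-uniformity
        float((rj**2).sum() / ns),             # length/size non-uniformity
        float(ns / n_vox),                     # run/zone percentage
        float((r / i**2).sum() / ns),          # low gray level emphasis
        float((r * i**2).sum() / ns),          # high gray level emphasis
        float((r / (i**2 * j**2)).sum() / ns), # short low
        float((r * i**2 / j**2).sum() / ns),   # short high
        float((r * j**2 / i**2).sum() / ns),   # long low
        float((r * i**2 * j**2).sum() / ns),   # long high
    ]
    return {f"{prefix}_{n}": v for n, v in zip(names, vals)}


_GLRLM_CORE = [
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "RunLengthNonUniformity", "RunPercentage", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]


def glrlm_features(m: GLRLMatrix) -> tuple[dict[str, float], set[str]]:
    names = [f"GLRLM_{x}" for x in _GLRLM]
    if m.counts.sum() == 0:
        return {k: float("nan") for k in names}, set(names)
    if m.aggregation is Aggregation.MERGE:
        # RP for merged matrices divides by voxel count x number of
        # contributing directions so it stays in (0, 1]
        n_active = sum(1 for c in m.counts if c.sum() > 0)
        feats = _rl_features(m.merged, m.voxel_count * n_active, "GLRLM", _GLRLM_CORE)
    else:
        per_dir = [
            _rl_features(r, m.voxel_count, "GLRLM", _GLRLM_CORE)
            for r in m.directional()
        ]
        feats = {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}
    flags = {k for k, v in feats.items() if not np.isfinite(v)}
    return feats, flags


_GLZLM_CORE = [
    "SmallZoneEmphasis", "LargeZoneEmphasis", "GrayLevelNonUniformity",
    "ZoneSizeNonUniformity", "ZonePercentage", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallZoneLowGrayLevelEmphasis",
    "SmallZoneHighGrayLevelEmphasis", "LargeZoneLowGrayLevelEmphasis",
    "LargeZoneHighGrayLevelEmphasis",
]


def glzlm_features(m: GLSZMatrix) -> tuple[dict[str, float], set[str]]:
    names = [f"GLZLM_{x}" for x in _GLZLM]
    if m.counts.sum() == 0:
        return {k: float("nan") for k in names}, set(names)
    feats = _rl_features(m.counts, m.voxel_count, "GLZLM", _GLZLM_CORE)
    # gray level variance over the zone-count distribution
    s = m.counts
    ns = s.sum()
    i = np.arange(1, s.shape[0] + 1, dtype=np.float64)
    p_i = s.sum(axis=1) / ns
    mu = float((i * p_i).sum())
    feats["GLZLM_GrayLevelVariance"] = float(((i - mu) ** 2 * p_i).sum())
    feats = {k: feats[k] for k in names}
    flags = {k for k, v in feats.items() if not np.isfinite(v)}
    return feats, flags


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_features(m: NGTDMatrix) -> tuple[dict[str, float], set[str]]:
    names = [f"NGTDM_{x}" for x in _NGTDM]
    if m.n_valid == 0:
        return {k: float("nan") for k in names}, set(names)
    p = m.p
    s = m.s
    nv = float(m.n_valid)
    present = p > 0
    i = np.arange(1, m.n_bins + 1, dtype=np.float64)
    ip = i[present]
    pp = p[present]
    sp = s[present]
    ngp = int(present.sum())
    ps = float((p * s).sum())
    coarseness = COARSENESS_CAP if ps == 0 else min(1.0 / ps, COARSENESS_CAP)
    if ngp > 1:
        di = ip[:, None] - ip[None, :]
        pij = pp[:, None] * pp[None, :]
        contrast = float((pij * di**2).sum() / (ngp * (ngp - 1)) * (s.sum() / nv))
        busy_den = float(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum())
        busyness = ps / busy_den if busy_den > 0 else 0.0
        pssum = (pp * sp)[:, None] + (pp * sp)[None, :]
        psum = pp[:, None] + pp[None, :]
        complexity = float((np.abs(di) * pssum / psum).sum() / nv)
        stot = float(s.sum())
        strength = float((psum * di**2).sum() / stot) if stot > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
    feats = {
        "NGTDM_Coarseness": float(coarseness),
        "NGTDM_Complexity": complexity,
        "NGTDM_Busyness": float(busyness),
        "NGTDM_Strength": strength,
        "NGTDM_Contrast": contrast,
    }
    flags = {k for k, v in feats.items() if not np.isfinite(v)}
    return feats, flags


# ---------------------------------------------------------------------------
# assembly


def extract(
    vol: ImageVolume,
    mask: ROIMask,
    d: DiscretizedROI,
    dialect: ExtractionDialect = DIALECT_A,
    fisher_kurtosis: bool = True,
) -> FeatureVector:
    """Assemble all 66 features from one preprocessed modality.

    Deterministic; degenerate features are NaN-valued and flagged, never
    dropped, so downstream agreement tables stay aligned.
    """
    values: dict[str, float] = {}
    flags: set[str] = set()

    values.update(shape_features(mask, dialect))

    hist_vals, hist_flags = histogram_features(vol, mask, d, fisher_kurtosis)
    values.update(hist_vals)
    flags |= hist_flags

    fv, fl = glcm_features(glcm(d, dialect.glcm_aggregation))
    values.update(fv)
    flags |= fl
    fv, fl = glrlm_features(glrlm(d, dialect.glrlm_aggregation))
    values.update(fv)
    flags |= fl
    fv, fl = glzlm_features(glszm(d))
    values.update(fv)
    flags |= fl
    fv, fl = ngtdm_features(ngtdm(d, dialect.ngtdm_edge_rule))
    values.update(fv)
    flags |= fl

    ordered = {name: values[name] for name in FEATURE_NAMES}
    return FeatureVector(values=ordered, degenerate_flags=flags)
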