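"""Construction of the four 3-D texture matrices (GLCM, GLRLM, GLSZM,
NGTDM) from a discretized ROI.

All matrices use the 26-neighborhood: GLCM offsets are the 13 unique
Chebyshev-distance-1 directions (the 26 neighbors halved by symmetry), runs
follow the same 13 directions, and zones are 26-connected components.
Out-of-ROI voxels break runs, zones and co-occurrence pairs, so the matrices
describe the ROI only.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import product

import numpy as np
from scipy import ndimage

from .preprocess import DiscretizedROI

__all__ = [
    "OFFSETS_13",
    "Aggregation",
    "NGTDMEdgeRule",
    "GLCMatrix",
    "GLRLMatrix",
    "GLSZMatrix",
    "NGTDMatrix",
    "glcm",
    "glrlm",
    "glszm",
    "ngtdm",
]

#: 13 unique 3-D offsets at Chebyshev distance 1 (lexicographically positive
#: half of the 26 neighbors).
OFFSETS_13: tuple[tuple[int, int, int], ...] = tuple(
    off for off in product((-1, 0, 1), repeat=3) if off > (0, 0, 0)
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class Aggregation(str, Enum):
    MERGE = "merge"
    AVERAGE = "average"


class NGTDMEdgeRule(str, Enum):
    """Which voxels count as valid centers for the NGTDM.

    ``include``: every ROI voxel with at least one in-ROI 26-neighbor.
    ``exclude``: only voxels whose full 26-neighborhood lies inside the ROI.
    """

    INCLUDE = "include"
    EXCLUDE = "exclude"


@dataclass
class GLCMatrix:
    """Per-direction symmetrized co-occurrence counts plus probabilities."""

    counts: np.ndarray  # (13, n_bins, n_bins) symmetrized pair counts
    aggregation: Aggregation
    n_bins: int
    degenerate: bool

    @property
    def merged_p(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts[0])
        return self.counts.sum(axis=0) / total

    def directional_p(self) -> list[np.ndarray]:
        """Normalized probability matrix for each direction with >= 1 pair."""
        out = []
        for c in self.counts:
            t = c.sum()
            if t > 0:
                out.append(c / t)
        return out


@dataclass
class GLRLMatrix:
    """Run counts r[direction, gray level, run length]; lengths 1..max."""

    counts: np.ndarray  # (13, n_bins, max_len)
    aggregation: Aggregation
    n_bins: int
    voxel_count: int

    @property
    def merged(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def directional(self) -> list[np.ndarray]:
        return [c for c in self.counts if c.sum() > 0]


@dataclass
class GLSZMatrix:
    """Zone counts s[gray level, zone size]; 26-connected zones."""

    counts: np.ndarray  # (n_bins, max_size)
    n_bins: int
    voxel_count: int


@dataclass
class NGTDMatrix:
    """Neighborhood gray-tone difference matrix.

    ``n[i]`` counts valid voxels of level i+1, ``s[i]`` sums their absolute
    deviation from the mean gray level of their in-ROI 26-neighbors.
    """

    n: np.ndarray  # (n_bins,) voxel counts per level
    s: np.ndarray  # (n_bins,) summed |i - neighborhood mean|
    n_valid: int
    n_bins: int

    @property
    def p(self) -> np.ndarray:
        if self.n_valid == 0:
            return np.zeros_like(self.s)
        return self.n / self.n_valid


def _pair_slices(off: tuple[int, int, int]):
    """Slices (a, b) such that arr[a] and arr[b] are voxel pairs at *off*."""
    a, b = [], []
    for o in off:
        if o > 0:
            a.append(slice(None, -o))
            b.append(slice(o, None))
        elif o < 0:
            a.append(slice(-o, None))
            b.append(slice(None, o))
        else:
            a.append(slice(None))
            b.append(slice(None))
    return tuple(a), tuple(b)


def glcm(d: DiscretizedROI, aggregation: Aggregation = Aggregation.MERGE) -> GLCMatrix:
    """Symmetrized gray-level co-occurrence counts for the 13 3-D offsets."""
    aggregation = Aggregation(aggregation)
    bins = d.bins
    n = d.n_bins
    counts = np.zeros((len(OFFSETS_13), n, n), dtype=np.float64)
    for k, off in enumerate(OFFSETS_13):
        sa, sb = _pair_slices(off)
        a = bins[sa].ravel()
        b = bins[sb].ravel()
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        flat = (a[valid] - 1) * n + (b[valid] - 1)
        c = np.bincount(flat, minlength=n * n).reshape(n, n).astype(np.float64)
        counts[k] = c + c.T  # symmetrization: add the reverse offset
    return GLCMatrix(
        counts=counts,
        aggregation=aggregation,
        n_bins=n,
        degenerate=counts.sum() == 0,
    )


def _runs_along(bins: np.ndarray, off: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Gray level and length of every maximal in-ROI run along direction *off*.

    Voxels on the same line share the residual ``index - t*off`` where ``t``
    is the step count along the first nonzero offset axis.
    """
    idx = np.argwhere(bins > 0)
    if idx.shape[0] == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    v = np.asarray(off)
    d0 = int(np.nonzero(v)[0][0])
    t = idx[:, d0] * v[d0]  # |v[d0]| == 1
    base = idx - t[:, None] * v
    order = np.lexsort((t, base[:, 2], base[:, 1], base[:, 0]))
    t = t[order]
    base = base[order]
    vals = bins[tuple(idx[order].T)]
    same_line = np.all(base[1:] == base[:-1], axis=1) & (np.diff(t) == 1)
    new_run = np.empty(vals.shape[0], dtype=bool)
    new_run[0] = True
    new_run[1:] = ~(same_line & (vals[1:] == vals[:-1]))
    starts = np.flatnonzero(new_run)
    lengths = np.diff(np.append(starts, vals.shape[0]))
    return vals[starts], lengths


def glrlm(d: DiscretizedROI, aggregation: Aggregation = Aggregation.MERGE) -> GLRLMatrix:
    """Maximal runs of equal bin value along each of the 13 directions."""
    aggregation = Aggregation(aggregation)
    n = d.n_bins
    max_len = max(d.bins.shape)
    counts = np.zeros((len(OFFSETS_13), n, max_len), dtype=np.float64)
    for k, off in enumerate(OFFSETS_13):
        levels, lengths = _runs_along(d.bins, off)
        if levels.size:
            np.add.at(counts[k], (levels - 1, lengths - 1), 1.0)
    return GLRLMatrix(
        counts=counts, aggregation=aggregation, n_bins=n, voxel_count=d.voxel_count
    )


def glszm(d: DiscretizedROI) -> GLSZMatrix:
    """26-connected zones of equal bin value within the ROI."""
    n = d.n_bins
    max_size = 1
    present = np.unique(d.bins[d.bins > 0])
    level_sizes: dict[int, np.ndarray] = {}
    for g in present:
        labeled, n_zones = ndimage.label(d.bins == g, structure=_STRUCT_26)
        if n_zones == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        level_sizes[int(g)] = sizes
        max_size = max(max_size, int(sizes.max()))
    counts = np.zeros((n, max_size), dtype=np.float64)
    for g, sizes in level_sizes.items():
        np.add.at(counts[g - 1], sizes - 1, 1.0)
    return GLSZMatrix(counts=counts, n_bins=n, voxel_count=d.voxel_count)


def ngtdm(
    d: DiscretizedROI, edge_rule: NGTDMEdgeRule = NGTDMEdgeRule.INCLUDE
) -> NGTDMatrix:
    """Per-level summed absolute difference from the 26-neighborhood mean."""
    edge_rule = NGTDMEdgeRule(edge_rule)
    roi = d.roi
    kernel = np.ones((3, 3, 3), dtype=np.float64)
    kernel[1, 1, 1] = 0.0
    nbr_sum = ndimage.correlate(
        (d.bins * roi).astype(np.float64), kernel, mode="constant", cval=0.0
    )
    nbr_cnt = ndimage.correlate(
        roi.astype(np.float64), kernel, mode="constant", cval=0.0
    )
    if edge_rule is NGTDMEdgeRule.INCLUDE:
        valid = roi & (nbr_cnt > 0)
    else:
        valid = roi & (nbr_cnt >= 26 - 0.5)
    n = np.zeros(d.n_bins, dtype=np.float64)
    s = np.zeros(d.n_bins, dtype=np.float64)
    if valid.any():
        levels = d.bins[valid]
        with np.errstate(invalid="ignore"):
            mean = nbr_sum[valid] / nbr_cnt[valid]
        dev = np.abs(levels - mean)
        np.add.at(n, levels - 1, 1.0)
        np.add.at(s, levels - 1, dev)
    return NGTDMatrix(n=n, s=s, n_valid=int(valid.sum()), n_bins=d.n_bins)
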