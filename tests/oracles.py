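"""Independent brute-force oracles used by the test suite.

Everything here is written with explicit Python loops over voxels, pairs and
matrix entries — deliberately naive and independent of the package's
vectorized implementations.
"""

from itertools import product
from math import log2, sqrt

import numpy as np

ALL_26 = [off for off in product((-1, 0, 1), repeat=3) if off != (0, 0, 0)]
HALF_13 = [off for off in ALL_26 if off > (0, 0, 0)]


def in_bounds(p, shape):
    return all(0 <= p[d] < shape[d] for d in range(3))


# ---------------------------------------------------------------------------
# matrices


def glcm_merged_counts(bins, n_bins):
    """Ordered in-ROI pair counts over all 26 Chebyshev-1 offsets."""
    m = np.zeros((n_bins, n_bins))
    shape = bins.shape
    for p in product(*(range(s) for s in shape)):
        a = bins[p]
        if a == 0:
            continue
        for off in ALL_26:
            q = tuple(p[d] + off[d] for d in range(3))
            if in_bounds(q, shape) and bins[q] > 0:
                m[a - 1, bins[q] - 1] += 1
    return m


def glcm_directional_counts(bins, n_bins):
    """Per half-offset symmetrized counts (ordered pairs over +-offset)."""
    out = []
    shape = bins.shape
    for off in HALF_13:
        m = np.zeros((n_bins, n_bins))
        for p in product(*(range(s) for s in shape)):
            a = bins[p]
            if a == 0:
                continue
            for o in (off, tuple(-x for x in off)):
                q = tuple(p[d] + o[d] for d in range(3))
                if in_bounds(q, shape) and bins[q] > 0:
                    m[a - 1, bins[q] - 1] += 1
        out.append(m)
    return out


def glrlm_directional_counts(bins, n_bins):
    """Run counts per direction by walking every line voxel by voxel."""
    shape = bins.shape
    max_len = max(shape)
    out = []
    for off in HALF_13:
        m = np.zeros((n_bins, max_len))
        for start in product(*(range(s) for s in shape)):
            prev = tuple(start[d] - off[d] for d in range(3))
            if in_bounds(prev, shape):
                continue  # not a line start
            p = start
            run_val, run_len = 0, 0
            while in_bounds(p, shape):
                v = bins[p]
                if v == run_val and v != 0:
                    run_len += 1
                else:
                    if run_val != 0:
                        m[run_val - 1, run_len - 1] += 1
                    run_val, run_len = v, (1 if v != 0 else 0)
                p = tuple(p[d] + off[d] for d in range(3))
            if run_val != 0:
                m[run_val - 1, run_len - 1] += 1
        out.append(m)
    return out


def glszm_zones(bins):
    """(gray level, size) of every 26-connected zone, by flood fill."""
    shape = bins.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for p in product(*(range(s) for s in shape)):
        if bins[p] == 0 or seen[p]:
            continue
        level = bins[p]
        stack = [p]
        seen[p] = True
        size = 0
        while stack:
            q = stack.pop()
            size += 1
            for off in ALL_26:
                nb = tuple(q[d] + off[d] for d in range(3))
                if in_bounds(nb, shape) and not seen[nb] and bins[nb] == level:
                    seen[nb] = True
                    stack.append(nb)
        zones.append((int(level), size))
    return zones


def glszm_counts(bins, n_bins):
    zones = glszm_zones(bins)
    max_size = max((s for _, s in zones), default=1)
    m = np.zeros((n_bins, max_size))
    for level, size in zones:
        m[level - 1, size - 1] += 1
    return m


def ngtdm_arrays(bins, n_bins, edge_rule="include"):
    """(n_i, s_i, N_valid) computed voxel by voxel."""
    shape = bins.shape
    n = np.zeros(n_bins)
    s = np.zeros(n_bins)
    n_valid = 0
    for p in product(*(range(sz) for sz in shape)):
        v = bins[p]
        if v == 0:
            continue
        nbrs = []
        for off in ALL_26:
            q = tuple(p[d] + off[d] for d in range(3))
            if in_bounds(q, shape) and bins[q] > 0:
                nbrs.append(bins[q])
        if edge_rule == "include":
            ok = len(nbrs) >= 1
        else:
            ok = len(nbrs) == 26
        if not ok:
            continue
        n_valid += 1
        n[v - 1] += 1
        s[v - 1] += abs(v - sum(nbrs) / len(nbrs))
    return n, s, n_valid


# ---------------------------------------------------------------------------
# literal-formula features


def glcm_features_from_p(p):
    ng = p.shape[0]
    mu = 0.0
    for i in range(ng):
        for j in range(ng):
            mu += (i + 1) * p[i, j]
    sigma2 = 0.0
    for i in range(ng):
        for j in range(ng):
            sigma2 += ((i + 1) - mu) ** 2 * p[i, j]
    p_diff = [0.0] * ng
    p_sum = [0.0] * (2 * ng + 1)
    for i in range(ng):
        for j in range(ng):
            p_diff[abs(i - j)] += p[i, j]
            p_sum[i + j + 2] += p[i, j]
    mu_diff = sum(k * p_diff[k] for k in range(ng))
    out = {}
    out["GLCM_Contrast"] = sum(
        (i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng)
    )
    cross = sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng))
    out["GLCM_Correlation"] = (cross - mu * mu) / sigma2 if sigma2 > 0 else float("nan")
    out["GLCM_Dissimilarity"] = sum(
        abs(i - j) * p[i, j] for i in range(ng) for j in range(ng)
    )
    out["GLCM_Energy"] = sum(p[i, j] ** 2 for i in range(ng) for j in range(ng))
    out["GLCM_Entropy"] = -sum(
        p[i, j] * log2(p[i, j]) for i in range(ng) for j in range(ng) if p[i, j] > 0
    )
    out["GLCM_InverseDifference"] = sum(
        p[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)
    )
    out["GLCM_Autocorrelation"] = cross
    out["GLCM_JointAverage"] = mu
    for power, name in ((4, "ClusterProminence"), (2, "ClusterTendency"), (3, "ClusterShade")):
        out[f"GLCM_{name}"] = sum(
            ((i + 1) + (j + 1) - 2 * mu) ** power * p[i, j]
            for i in range(ng)
            for j in range(ng)
        )
    out["GLCM_DifferenceVariance"] = sum(
        (k - mu_diff) ** 2 * p_diff[k] for k in range(ng)
    )
    out["GLCM_DifferenceEntropy"] = -sum(
        q * log2(q) for q in p_diff if q > 0
    )
    out["GLCM_InverseVariance"] = sum(
        p[i, j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
    )
    out["GLCM_SumEntropy"] = -sum(q * log2(q) for q in p_sum if q > 0)
    out["GLCM_JointVariance"] = sum(
        ((i + 1) - mu) ** 2 * p[i, j] for i in range(ng) for j in range(ng)
    )
    out["GLCM_JointMaximum"] = max(p[i, j] for i in range(ng) for j in range(ng))
    out["GLCM_NormalizedInverseDifference"] = sum(
        p[i, j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
    )
    return out


def glcm_features(bins, n_bins, aggregation="merge"):
    if aggregation == "merge":
        m = glcm_merged_counts(bins, n_bins)
        return glcm_features_from_p(m / m.sum())
    dirs = [m for m in glcm_directional_counts(bins, n_bins) if m.sum() > 0]
    feats = [glcm_features_from_p(m / m.sum()) for m in dirs]
    return {k: sum(f[k] for f in feats) / len(feats) for k in feats[0]}


def _rl_features_from_counts(r, n_vox, prefix, names):
    ng, nl = r.shape
    ns = r.sum()
    out = {}
    sums = {name: 0.0 for name in names}
    for i in range(ng):
        for j in range(nl):
            if r[i, j] == 0:
                continue
            gi, lj = i + 1.0, j + 1.0
            sums[names[0]] += r[i, j] / lj**2
            sums[names[1]] += r[i, j] * lj**2
            sums[names[5]] += r[i, j] / gi**2
            sums[names[6]] += r[i, j] * gi**2
            sums[names[7]] += r[i, j] / (gi**2 * lj**2)
            sums[names[8]] += r[i, j] * gi**2 / lj**2
            sums[names[9]] += r[i, j] * lj**2 / gi**2
            sums[names[10]] += r[i, j] * gi**2 * lj**2
    for i in range(ng):
        sums[names[2]] += r[i, :].sum() ** 2
    for j in range(nl):
        sums[names[3]] += r[:, j].sum() ** 2
    for name in names:
        if name != names[4]:
            out[f"{prefix}_{name}"] = sums[name] / ns
    out[f"{prefix}_{names[4]}"] = ns / n_vox
    return out


GLRLM_NAMES = [
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "RunLengthNonUniformity", "RunPercentage", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]

GLZLM_NAMES = [
    "SmallZoneEmphasis", "LargeZoneEmphasis", "GrayLevelNonUniformity",
    "ZoneSizeNonUniformity", "ZonePercentage", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallZoneLowGrayLevelEmphasis",
    "SmallZoneHighGrayLevelEmphasis", "LargeZoneLowGrayLevelEmphasis",
    "LargeZoneHighGrayLevelEmphasis",
]


def glrlm_features(bins, n_bins, aggregation="merge"):
    n_vox = int((bins > 0).sum())
    dirs = glrlm_directional_counts(bins, n_bins)
    active = [m for m in dirs if m.sum() > 0]
    if aggregation == "merge":
        merged = sum(active)
        return _rl_features_from_counts(
            merged, n_vox * len(active), "GLRLM", GLRLM_NAMES
        )
    feats = [
        _rl_features_from_counts(m, n_vox, "GLRLM", GLRLM_NAMES) for m in active
    ]
    return {k: sum(f[k] for f in feats) / len(feats) for k in feats[0]}


def glzlm_features(bins, n_bins):
    n_vox = int((bins > 0).sum())
    s = glszm_counts(bins, n_bins)
    out = _rl_features_from_counts(s, n_vox, "GLZLM", GLZLM_NAMES)
    ns = s.sum()
    mu = 0.0
    for i in range(n_bins):
        mu += (i + 1) * s[i, :].sum() / ns
    glv = 0.0
    for i in range(n_bins):
        glv += ((i + 1) - mu) ** 2 * s[i, :].sum() / ns
    out["GLZLM_GrayLevelVariance"] = glv
    return out


def ngtdm_features(bins, n_bins, edge_rule="include", coarseness_cap=1e6):
    n, s, n_valid = ngtdm_arrays(bins, n_bins, edge_rule)
    if n_valid == 0:
        nan = float("nan")
        return {
            f"NGTDM_{k}": nan
            for k in ("Coarseness", "Complexity", "Busyness", "Strength", "Contrast")
        }
    p = [ni / n_valid for ni in n]
    levels = [i for i in range(n_bins) if p[i] > 0]
    ngp = len(levels)
    ps = sum(p[i] * s[i] for i in range(n_bins))
    coarseness = coarseness_cap if ps == 0 else min(1.0 / ps, coarseness_cap)
    contrast = busyness = complexity = strength = 0.0
    if ngp > 1:
        acc = 0.0
        for i in levels:
            for j in levels:
                acc += p[i] * p[j] * (i - j) ** 2
        contrast = acc / (ngp * (ngp - 1)) * (sum(s) / n_valid)
        den = 0.0
        for i in levels:
            for j in levels:
                den += abs((i + 1) * p[i] - (j + 1) * p[j])
        busyness = ps / den if den > 0 else 0.0
        for i in levels:
            for j in levels:
                complexity += (
                    abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
                )
        complexity /= n_valid
        stot = sum(s)
        if stot > 0:
            acc = 0.0
            for i in levels:
                for j in levels:
                    acc += (p[i] + p[j]) * (i - j) ** 2
            strength = acc / stot
    return {
        "NGTDM_Coarseness": coarseness,
        "NGTDM_Complexity": complexity,
        "NGTDM_Busyness": busyness,
        "NGTDM_Strength": strength,
        "NGTDM_Contrast": contrast,
    }


def all_texture_features(bins, n_bins, glcm_agg="merge", glrlm_agg="merge", edge_rule="include"):
    out = {}
    out.update(glcm_features(bins, n_bins, glcm_agg))
    out.update(glrlm_features(bins, n_bins, glrlm_agg))
    out.update(glzlm_features(bins, n_bins))
    out.update(ngtdm_features(bins, n_bins, edge_rule))
    return out


# ---------------------------------------------------------------------------
# ICC by explicit sums of squares


def icc_oracle(x):
    """Two-way absolute-agreement single-measurement ICC from first
    principles (loops, no shortcuts)."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = sum(x[i, j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(x[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(x[i, j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((r - grand) ** 2 for r in row)
    ss_cols = n * sum((c - grand) ** 2 for c in col)
    ss_err = sum(
        (x[i, j] - row[i] - col[j] + grand) ** 2 for i in range(n) for j in range(k)
    )
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e))


# ---------------------------------------------------------------------------
# quantile mapping (1-D, sort based)


def quantile_map_oracle(values, src, ref, levels):
    """Map values via paired sort-based quantiles of src/ref."""
    src_q = np.quantile(np.sort(src), levels)
    ref_q = np.quantile(np.sort(ref), levels)
    return np.interp(values, src_q, ref_q)


def random_roi(rng, max_side=8, max_bins=8):
    """A random discretized ROI for oracle-equivalence tests."""
    shape = tuple(int(rng.integers(2, max_side + 1)) for _ in range(3))
    n_bins = int(rng.integers(2, max_bins + 1))
    bins = rng.integers(1, n_bins + 1, size=shape).astype(np.int32)
    roi = rng.random(shape) < 0.7
    if not roi.any():
        roi.flat[int(rng.integers(roi.size))] = True
    bins[~roi] = 0
    return bins, n_bins
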