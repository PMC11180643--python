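import numpy as np
import pytest

import oracles
from radagree.features import (
    BUILTIN_DIALECTS,
    CATEGORY_COUNTS,
    DIALECT_A,
    DIALECT_B,
    FEATURE_NAMES,
    Category,
    ExtractionDialect,
    FeatureVector,
    SurfaceAlgorithm,
    extract,
    glcm_features,
    glrlm_features,
    glzlm_features,
    histogram_features,
    ngtdm_features,
    shape_features,
)
from radagree.image_model import ImageVolume, Modality, ROIMask
from radagree.preprocess import discretize
from radagree.texture_matrices import (
    OFFSETS_13,
    Aggregation,
    GLCMatrix,
    GLRLMatrix,
    GLSZMatrix,
    glcm,
    glrlm,
    glszm,
    ngtdm,
)
from test_texture_matrices import droi, random_droi


def test_feature_names_layout():
    assert len(FEATURE_NAMES) == 66
    counts = {}
    for name in FEATURE_NAMES:
        cat = Category(name.split("_", 1)[0])
        counts[cat] = counts.get(cat, 0) + 1
    assert counts == CATEGORY_COUNTS


class TestShape:
    def cube_mask(self, spacing=(1, 1, 1)):
        m = np.zeros((12, 12, 12), dtype=bool)
        m[1:11, 1:11, 1:11] = True
        return ROIMask(m, spacing)

    def test_cube_closed_forms_voxel_face(self):
        f = shape_features(self.cube_mask(), DIALECT_B)
        assert f["SHAPE_VoxelVolume"] == pytest.approx(1000.0)
        assert f["SHAPE_SurfaceArea"] == pytest.approx(600.0)
        expected_sph = (36 * np.pi * 1e6) ** (1 / 3) / 600.0
        assert f["SHAPE_Sphericity"] == pytest.approx(expected_sph)
        assert expected_sph == pytest.approx(0.806, abs=5e-3)

    def test_cube_max_diameter_brute_force(self):
        f = shape_features(self.cube_mask(), DIALECT_B)
        mask = self.cube_mask().data
        pts = np.argwhere(mask)
        # brute force over surface voxels: drop interior voxels first
        surf = []
        for p in pts:
            i, j, k = p
            if np.any(p == 1) or np.any(p == 10):
                surf.append(p)
        surf = np.asarray(surf, dtype=float)
        best = 0.0
        for a in range(len(surf)):
            d = np.sqrt(((surf[a] - surf) ** 2).sum(axis=1)).max()
            best = max(best, d)
        assert f["SHAPE_Maximum3DDiameter"] == pytest.approx(best)
        assert best == pytest.approx(np.sqrt(3 * 81))

    def test_spacing_scaling(self):
        f1 = shape_features(self.cube_mask(), DIALECT_B)
        f2 = shape_features(self.cube_mask(spacing=(2, 2, 2)), DIALECT_B)
        assert f2["SHAPE_VoxelVolume"] == pytest.approx(8 * f1["SHAPE_VoxelVolume"])
        assert f2["SHAPE_SurfaceArea"] == pytest.approx(4 * f1["SHAPE_SurfaceArea"])
        assert f2["SHAPE_Sphericity"] == pytest.approx(f1["SHAPE_Sphericity"])

    def test_mesh_area_close_to_analytic_for_sphere(self):
        n = 41
        i, j, k = np.indices((n, n, n))
        c = (n - 1) / 2
        r = 15.0
        mask = ROIMask((i - c) ** 2 + (j - c) ** 2 + (k - c) ** 2 <= r**2, (1, 1, 1))
        f = shape_features(mask, DIALECT_A)
        # marching cubes on a binary mask is jagged: allow ~10% overestimate
        assert f["SHAPE_SurfaceArea"] == pytest.approx(4 * np.pi * r**2, rel=0.10)
        assert 0.85 < f["SHAPE_Sphericity"] <= 1.05

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            shape_features(ROIMask(np.zeros((3, 3, 3)), (1, 1, 1)), DIALECT_A)


class TestHistogram:
    def _vals(self, values, n_bins=64):
        data = np.asarray(values, dtype=float).reshape(1, 1, -1)
        vol = ImageVolume(data, (1, 1, 1))
        mask = ROIMask(np.ones_like(data), (1, 1, 1))
        d = discretize(vol, mask, n_bins)
        return histogram_features(vol, mask, d)

    def test_simple_stats(self):
        vals, flags = self._vals([1.0, 2.0, 3.0])
        assert vals["HISTOGRAM_Mean"] == pytest.approx(2.0)
        assert vals["HISTOGRAM_Median"] == pytest.approx(2.0)
        assert vals["HISTOGRAM_Range"] == pytest.approx(2.0)
        assert vals["HISTOGRAM_Variance"] == pytest.approx(2.0 / 3.0)  # population
        assert vals["HISTOGRAM_Energy"] == pytest.approx(1 + 4 + 9)
        assert not flags

    def test_constant_roi_degeneracies(self):
        vals, flags = self._vals([5.0] * 27)
        assert vals["HISTOGRAM_Entropy"] == pytest.approx(0.0)
        assert vals["HISTOGRAM_Uniformity"] == pytest.approx(1.0)
        assert vals["HISTOGRAM_Variance"] == pytest.approx(0.0)
        assert np.isnan(vals["HISTOGRAM_Skewness"])
        assert {"HISTOGRAM_Skewness", "HISTOGRAM_Kurtosis"} <= flags

    def test_normal_sample_moments(self):
        rng = np.random.default_rng(42)
        vals, _ = self._vals(rng.standard_normal(10_000))
        assert abs(vals["HISTOGRAM_Skewness"]) < 0.1
        assert abs(vals["HISTOGRAM_Kurtosis"]) < 0.2  # Fisher (excess)

    def test_kurtosis_convention_switch(self):
        data = np.asarray([1.0, 2.0, 2.0, 3.0, 7.0]).reshape(1, 1, -1)
        vol = ImageVolume(data, (1, 1, 1))
        mask = ROIMask(np.ones_like(data), (1, 1, 1))
        d = discretize(vol, mask, 4)
        fisher, _ = histogram_features(vol, mask, d, fisher_kurtosis=True)
        pearson, _ = histogram_features(vol, mask, d, fisher_kurtosis=False)
        assert pearson["HISTOGRAM_Kurtosis"] == pytest.approx(
            fisher["HISTOGRAM_Kurtosis"] + 3.0
        )

    def test_percentiles_and_rmad(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=501)
        vals, _ = self._vals(x)
        assert vals["HISTOGRAM_Percentile10"] == pytest.approx(np.percentile(x, 10))
        assert vals["HISTOGRAM_Percentile90"] == pytest.approx(np.percentile(x, 90))
        band = x[(x >= np.percentile(x, 10)) & (x <= np.percentile(x, 90))]
        assert vals["HISTOGRAM_RobustMeanAbsoluteDeviation"] == pytest.approx(
            np.abs(band - band.mean()).mean()
        )


class TestGLCMFeatures:
    def test_constant_roi(self):
        vals, flags = glcm_features(glcm(droi(np.ones((3, 3, 3), dtype=int))))
        assert vals["GLCM_Contrast"] == pytest.approx(0.0)
        assert vals["GLCM_Dissimilarity"] == pytest.approx(0.0)
        assert vals["GLCM_Energy"] == pytest.approx(1.0)
        assert vals["GLCM_Entropy"] == pytest.approx(0.0)
        assert vals["GLCM_JointMaximum"] == pytest.approx(1.0)
        assert "GLCM_Correlation" in flags  # zero marginal variance

    def test_checkerboard_single_direction_contrast(self):
        i, j, k = np.indices((4, 4, 4))
        bins = ((i + j + k) % 2 + 1).astype(np.int32)
        d = droi(bins, 2)
        full = glcm(d)
        kdir = OFFSETS_13.index((0, 0, 1))
        counts = np.zeros_like(full.counts)
        counts[kdir] = full.counts[kdir]
        single = GLCMatrix(counts=counts, aggregation=Aggregation.MERGE, n_bins=2, degenerate=False)
        # along one axis every neighbor alternates: all mass off-diagonal
        assert single.merged_p[0, 0] == 0 and single.merged_p[1, 1] == 0
        vals, _ = glcm_features(single)
        assert vals["GLCM_Contrast"] == pytest.approx(1.0)  # (delta bin)^2

    def test_correlation_bounded(self, rng):
        for _ in range(20):
            d = random_droi(rng)
            vals, flags = glcm_features(glcm(d))
            if "GLCM_Correlation" not in flags and np.isfinite(vals["GLCM_Correlation"]):
                assert -1 - 1e-9 <= vals["GLCM_Correlation"] <= 1 + 1e-9

    def test_degenerate_matrix_flags_all(self):
        vals, flags = glcm_features(glcm(droi(np.ones((1, 1, 1), dtype=int))))
        assert len(flags) == 18
        assert all(np.isnan(v) for v in vals.values())


class TestGLRLMFeatures:
    def test_single_run_closed_form(self):
        counts = np.zeros((13, 1, 5))
        counts[0, 0, 4] = 1  # one run, gray 1, length 5
        m = GLRLMatrix(counts=counts, aggregation=Aggregation.MERGE, n_bins=1, voxel_count=5)
        vals, _ = glrlm_features(m)
        assert vals["GLRLM_ShortRunEmphasis"] == pytest.approx(1 / 25)
        assert vals["GLRLM_LongRunEmphasis"] == pytest.approx(25.0)
        assert vals["GLRLM_RunPercentage"] == pytest.approx(0.2)

    def test_constant_roi_lgre(self):
        for agg in Aggregation:
            vals, _ = glrlm_features(glrlm(droi(np.ones((4, 3, 2), dtype=int)), agg))
            assert vals["GLRLM_LowGrayLevelRunEmphasis"] == pytest.approx(1.0)

    @pytest.mark.parametrize("agg", list(Aggregation))
    def test_matches_literal_oracle(self, rng, agg):
        for _ in range(5):
            d = random_droi(rng, max_side=6)
            vals, _ = glrlm_features(glrlm(d, agg))
            expected = oracles.glrlm_features(d.bins, d.n_bins, agg.value)
            for k, v in expected.items():
                assert vals[k] == pytest.approx(v, rel=1e-10), k


class TestGLZLMFeatures:
    def test_single_zone_closed_form(self):
        counts = np.zeros((1, 27))
        counts[0, 26] = 1
        m = GLSZMatrix(counts=counts, n_bins=1, voxel_count=27)
        vals, _ = glzlm_features(m)
        assert vals["GLZLM_SmallZoneEmphasis"] == pytest.approx(1 / 27**2)
        assert vals["GLZLM_LargeZoneEmphasis"] == pytest.approx(27**2)
        assert vals["GLZLM_ZonePercentage"] == pytest.approx(1 / 27)
        assert vals["GLZLM_GrayLevelVariance"] == pytest.approx(0.0)

    def test_matches_literal_oracle(self, rng):
        for _ in range(5):
            d = random_droi(rng, max_side=6)
            vals, _ = glzlm_features(glszm(d))
            expected = oracles.glzlm_features(d.bins, d.n_bins)
            for k, v in expected.items():
                assert vals[k] == pytest.approx(v, rel=1e-10), k


class TestNGTDMFeatures:
    def test_constant_roi_caps(self):
        vals, _ = ngtdm_features(ngtdm(droi(np.ones((3, 3, 3), dtype=int))))
        assert vals["NGTDM_Coarseness"] == pytest.approx(1e6)
        assert vals["NGTDM_Busyness"] == pytest.approx(0.0)
        assert vals["NGTDM_Complexity"] == pytest.approx(0.0)
        assert vals["NGTDM_Strength"] == pytest.approx(0.0)

    def test_hand_oracle_1x1x3(self):
        bins = np.array([1, 2, 1]).reshape(1, 1, 3)
        vals, _ = ngtdm_features(ngtdm(droi(bins, 2)))
        # p = (2/3, 1/3), s = (2, 1): sum(p*s) = 5/3
        assert vals["NGTDM_Coarseness"] == pytest.approx(3 / 5)
        assert vals["NGTDM_Busyness"] == pytest.approx(0.0)  # |1*2/3 - 2*1/3| = 0
        assert vals["NGTDM_Strength"] == pytest.approx(2 / 3)
        assert vals["NGTDM_Contrast"] == pytest.approx(2 / 9)

    def test_count_scaling_relations(self, rng):
        # replicating every voxel c times scales n, s and N_valid by c;
        # p is normalized so Contrast and Complexity are invariant, while
        # Coarseness and Strength scale by 1/c and Busyness by c (their s
        # terms are sums, not averages)
        from radagree.texture_matrices import NGTDMatrix

        d = random_droi(rng)
        m = ngtdm(d)
        vals1, _ = ngtdm_features(m)
        if vals1["NGTDM_Coarseness"] >= 1e6:
            pytest.skip("degenerate (capped) input")
        c = 3
        scaled = NGTDMatrix(n=m.n * c, s=m.s * c, n_valid=m.n_valid * c, n_bins=m.n_bins)
        vals2, _ = ngtdm_features(scaled)
        assert vals2["NGTDM_Contrast"] == pytest.approx(vals1["NGTDM_Contrast"], rel=1e-12)
        assert vals2["NGTDM_Complexity"] == pytest.approx(vals1["NGTDM_Complexity"], rel=1e-12)
        assert vals2["NGTDM_Coarseness"] == pytest.approx(vals1["NGTDM_Coarseness"] / c, rel=1e-12)
        assert vals2["NGTDM_Strength"] == pytest.approx(vals1["NGTDM_Strength"] / c, rel=1e-12)
        assert vals2["NGTDM_Busyness"] == pytest.approx(vals1["NGTDM_Busyness"] * c, rel=1e-12)


def _phantom_pair(name, phantoms, n_bins=64):
    vol, mask = phantoms[name]
    return vol, mask, discretize(vol, mask, n_bins)


class TestExtract:
    def test_66_values_in_order(self, phantoms):
        vol, mask, d = _phantom_pair("cube", phantoms)
        fv = extract(vol, mask, d, DIALECT_A)
        assert tuple(fv.values) == FEATURE_NAMES
        assert len(fv) == 66
        cats = {}
        for name, cat in fv.categories.items():
            cats[cat] = cats.get(cat, 0) + 1
        assert cats == CATEGORY_COUNTS

    def test_deterministic(self, phantoms):
        vol, mask, d = _phantom_pair("cube", phantoms)
        a = extract(vol, mask, d, DIALECT_B)
        b = extract(vol, mask, d, DIALECT_B)
        assert a.values == b.values
        assert a.degenerate_flags == b.degenerate_flags

    def test_dialects_share_histogram_features(self, phantoms):
        vol, mask, d = _phantom_pair("checkerboard", phantoms)
        fa = extract(vol, mask, d, DIALECT_A)
        fb = extract(vol, mask, d, DIALECT_B)
        for name in FEATURE_NAMES:
            if name.startswith("HISTOGRAM_"):
                assert fa.values[name] == pytest.approx(fb.values[name], abs=0.0)

    def test_dialects_on_constant_sphere(self):
        # constant-intensity sphere: GLCM/GLZLM/NGTDM/HISTOGRAM agree across
        # dialects; shape differs only through the surface algorithm.  (GLRLM
        # merge vs average differ even here because run-length distributions
        # are direction-dependent on any 3-D shape.)
        n = 15
        i, j, k = np.indices((n, n, n))
        c = (n - 1) / 2
        mask = ROIMask((i - c) ** 2 + (j - c) ** 2 + (k - c) ** 2 <= 36, (1, 1, 1))
        vol = ImageVolume(np.full((n, n, n), 9.0), (1, 1, 1))
        d = discretize(vol, mask, 64)
        fa = extract(vol, mask, d, DIALECT_A)
        fb = extract(vol, mask, d, DIALECT_B)
        for name in FEATURE_NAMES:
            cat = name.split("_", 1)[0]
            va, vb = fa.values[name], fb.values[name]
            if cat in ("GLCM", "GLZLM", "NGTDM", "HISTOGRAM"):
                if np.isnan(va):
                    assert np.isnan(vb)
                else:
                    assert va == pytest.approx(vb, rel=1e-12), name
        assert fa.values["SHAPE_VoxelVolume"] == fb.values["SHAPE_VoxelVolume"]
        assert fa.values["SHAPE_Maximum3DDiameter"] == fb.values["SHAPE_Maximum3DDiameter"]
        assert fa.values["SHAPE_SurfaceArea"] != fb.values["SHAPE_SurfaceArea"]

    def test_intensity_shift_invariance(self, rng):
        data = rng.normal(100, 20, size=(8, 8, 8))
        mask = ROIMask(np.ones((8, 8, 8)), (1, 1, 1))
        v1 = ImageVolume(data, (1, 1, 1))
        v2 = ImageVolume(data + 500.0, (1, 1, 1))
        f1 = extract(v1, mask, discretize(v1, mask, 16), DIALECT_A)
        f2 = extract(v2, mask, discretize(v2, mask, 16), DIALECT_A)
        for name in FEATURE_NAMES:
            if name.split("_")[0] in ("GLCM", "GLRLM", "GLZLM", "NGTDM"):
                assert f1.values[name] == pytest.approx(f2.values[name], rel=1e-12), name

    def test_rotation_invariance_merge(self, rng):
        data = rng.normal(size=(7, 7, 7))
        maskarr = rng.random((7, 7, 7)) < 0.6
        maskarr[3, 3, 3] = True
        vol = ImageVolume(data, (1, 1, 1))
        mask = ROIMask(maskarr, (1, 1, 1))
        f1 = extract(vol, mask, discretize(vol, mask, 8), DIALECT_A)
        vol_r = ImageVolume(np.rot90(data).copy(), (1, 1, 1))
        mask_r = ROIMask(np.rot90(maskarr).copy(), (1, 1, 1))
        f2 = extract(vol_r, mask_r, discretize(vol_r, mask_r, 8), DIALECT_A)
        for name in FEATURE_NAMES:
            if name.split("_")[0] in ("GLCM", "GLRLM", "GLZLM", "NGTDM"):
                assert f1.values[name] == pytest.approx(f2.values[name], rel=1e-10), name

    def test_feature_vector_validation(self):
        with pytest.raises(ValueError):
            FeatureVector(values={"SHAPE_VoxelVolume": 1.0})

    def test_builtin_dialect_axes(self):
        assert DIALECT_A.glcm_aggregation is Aggregation.MERGE
        assert DIALECT_B.glcm_aggregation is Aggregation.AVERAGE
        assert DIALECT_A.surface_algorithm is SurfaceAlgorithm.MESH
        assert DIALECT_B.surface_algorithm is SurfaceAlgorithm.VOXEL_FACE
        assert DIALECT_A.grid_anchor == "corner" and DIALECT_B.grid_anchor == "center"
        assert set(BUILTIN_DIALECTS) == {"A", "B"}


@pytest.mark.parametrize("seed", range(10))
def test_oracle_equivalence_spot(seed):
    """Spot check of the full oracle-equivalence sweep (100-ROI version in
    the acceptance suite)."""
    rng = np.random.default_rng(1000 + seed)
    d = random_droi(rng)
    got, _ = glcm_features(glcm(d, Aggregation.MERGE))
    expected = oracles.glcm_features(d.bins, d.n_bins, "merge")
    for k, v in expected.items():
        if np.isnan(v):
            assert np.isnan(got[k]), k
        else:
            assert got[k] == pytest.approx(v, rel=1e-10, abs=1e-12), k
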