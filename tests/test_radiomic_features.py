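import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kurtosis as sp_kurtosis
from scipy.stats import skew as sp_skew

from radiopath.image_io import ImageVolume, RoiMask
from radiopath.radiomic_features import (
    FEATURE_CATEGORIES,
    GLCM_OFFSETS,
    ExtractionConfig,
    discretize,
    extract_all,
    glcm,
    glcm_features,
    global_features,
    glszm,
    glszm_features,
    histogram_features,
    lung_cancer_specific_features,
    mpp,
    shape_features,
)
from radiopath.synthetic_data import PhantomSpec, make_tumor_phantom

from .oracles import glcm_bruteforce, glszm_bruteforce

# closed form: unit cube, A=6, V=1 → A / (4π (3V/4π)^(2/3))
CUBE_DISPROPORTION = 6.0 / (4.0 * math.pi * (3.0 / (4.0 * math.pi)) ** (2.0 / 3.0))


def _vol_mask(data, mask, spacing=(1.0, 1.0, 1.0)):
    return ImageVolume(np.asarray(data, float), spacing), RoiMask(np.asarray(mask), spacing)


class TestDiscretize:
    def test_two_values_two_bins(self):
        np.testing.assert_array_equal(discretize(np.array([0.0, 100.0]), 2), [1, 2])

    def test_constant_input_all_level_one(self):
        np.testing.assert_array_equal(discretize(np.full(9, 7.0), 8), np.ones(9))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_floor_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(0, 100, size=100)
        n_bins = 8
        got = discretize(v, n_bins)
        lo, hi = v.min(), v.max()
        expected = np.minimum(np.floor((v - lo) / (hi - lo) * n_bins).astype(int) + 1, n_bins)
        np.testing.assert_array_equal(got, expected)
        assert got.min() >= 1 and got.max() == n_bins


class TestGlobalFeatures:
    def test_volume_of_1000_unit_voxels_is_1ml(self):
        vol, mask = _vol_mask(np.zeros((10, 10, 10)), np.ones((10, 10, 10)))
        assert global_features(vol, mask)["volume_ml"] == pytest.approx(1.0)

    def test_water_roi_mass_is_1g(self):
        vol, mask = _vol_mask(np.zeros((10, 10, 10)), np.ones((10, 10, 10)))
        assert global_features(vol, mask)["mass_g"] == pytest.approx(1.0)

    def test_mixed_hu_mass_matches_per_voxel_sum(self, rng):
        data = rng.normal(-100, 400, size=(6, 6, 6))
        mask = rng.random((6, 6, 6)) < 0.5
        mask[0, 0, 0] = True
        vol, m = _vol_mask(data, mask, spacing=(0.8, 0.8, 2.0))
        expected = sum(
            max((data[i, j, k] + 1000) / 1000, 0.0) * 0.8 * 0.8 * 2.0 / 1000
            for i, j, k in zip(*np.nonzero(mask))
        )
        assert global_features(vol, m)["mass_g"] == pytest.approx(expected, rel=1e-12)


class TestHistogramFeatures:
    def test_constant_roi_degenerate_values(self):
        f = histogram_features(np.full(50, 25.0))
        assert f["energy"] == 1.0
        assert f["entropy"] == 0.0
        assert f["range"] == 0.0
        assert f["iqr"] == 0.0
        assert math.isnan(f["kurtosis"]) and math.isnan(f["skewness"])

    def test_two_level_symmetry(self):
        f = histogram_features(np.array([0.0, 0.0, 100.0, 100.0]), ExtractionConfig(n_bins=2))
        assert f["energy"] == pytest.approx(0.5)
        assert f["range"] == 100.0
        assert f["median"] == 50.0
        assert f["entropy"] == pytest.approx(1.0)

    def test_random_values_match_direct_formulas(self, rng):
        v = rng.normal(-50, 200, size=500)
        f = histogram_features(v)
        assert f["mean"] == pytest.approx(v.mean())
        assert f["sd"] == pytest.approx(v.std(ddof=1))
        assert f["range"] == pytest.approx(v.max() - v.min())
        assert f["kurtosis"] == pytest.approx(sp_kurtosis(v))
        assert f["skewness"] == pytest.approx(sp_skew(v))
        assert f["iqr"] == pytest.approx(np.percentile(v, 75) - np.percentile(v, 25))
        for q, name in [(2.5, "hu_p2_5"), (25, "hu_p25"), (50, "median"), (75, "hu_p75"), (97.5, "hu_p97_5")]:
            assert f[name] == pytest.approx(np.percentile(v, q))
        # energy/entropy from an independent histogram computation
        lev = discretize(v, 32)
        p = np.bincount(lev, minlength=33)[1:] / v.size
        assert f["energy"] == pytest.approx((p**2).sum())
        assert f["entropy"] == pytest.approx(-(p[p > 0] * np.log2(p[p > 0])).sum())

    def test_ordering_invariance(self, rng):
        v = rng.normal(size=200)
        f1, f2 = histogram_features(v), histogram_features(v[::-1].copy())
        for k in f1:
            if not math.isnan(f1[k]):
                assert f1[k] == pytest.approx(f2[k])


class TestMpp:
    def test_mean_of_strictly_positive(self):
        assert mpp(np.array([-100.0, 50.0, 150.0])) == pytest.approx(100.0)

    def test_no_positive_voxels_is_missing(self):
        assert math.isnan(mpp(np.array([-10.0, 0.0, -5.0])))

    def test_random_equals_filtered_mean(self, rng):
        v = rng.normal(0, 100, size=300)
        assert mpp(v) == pytest.approx(v[v > 0].mean())

    def test_composition_fractions_defined_without_positives(self):
        f = lung_cancer_specific_features(np.full(10, -500.0), 1.0)
        assert math.isnan(f["mpp"])
        assert f["pct_positive_voxels"] == 0.0
        assert f["pct_air_voxels"] == 100.0


class TestShapeFeatures:
    def test_single_voxel_closed_forms(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        f = shape_features(RoiMask(m, (1, 1, 1)))
        assert f["surface_area_mm2"] == pytest.approx(6.0, abs=1e-9)
        assert f["max_3d_diameter_mm"] == 0.0
        assert f["spherical_disproportion"] == pytest.approx(CUBE_DISPROPORTION, abs=1e-9)

    def test_cube_closed_forms_and_scale_invariance(self):
        m = np.zeros((12, 12, 12), bool)
        m[1:11, 1:11, 1:11] = True
        f = shape_features(RoiMask(m, (1, 1, 1)))
        assert f["surface_area_mm2"] == pytest.approx(600.0, abs=1e-9)
        assert f["spherical_disproportion"] == pytest.approx(CUBE_DISPROPORTION, abs=1e-9)
        assert f["sphericity"] == pytest.approx(1.0 / CUBE_DISPROPORTION, abs=1e-9)

    def test_345_triangle_diameter(self):
        m = np.zeros((6, 6, 6), bool)
        m[0, 0, 0] = m[3, 4, 0] = True
        f = shape_features(RoiMask(m, (1, 1, 1)))
        assert f["max_3d_diameter_mm"] == pytest.approx(5.0)

    def test_spacing_scaling_laws(self, rng):
        m = rng.random((8, 8, 8)) < 0.5
        m[4, 4, 4] = True
        f1 = shape_features(RoiMask(m, (1, 1, 1)))
        k = 2.5
        fk = shape_features(RoiMask(m, (k, k, k)))
        assert fk["surface_area_mm2"] == pytest.approx(k**2 * f1["surface_area_mm2"])
        assert fk["max_3d_diameter_mm"] == pytest.approx(k * f1["max_3d_diameter_mm"])
        assert fk["spherical_disproportion"] == pytest.approx(f1["spherical_disproportion"])
        assert fk["sphericity"] == pytest.approx(f1["sphericity"])

    def test_translation_invariance(self, rng):
        m = np.zeros((12, 12, 12), bool)
        m[2:5, 2:6, 2:4] = rng.random((3, 4, 2)) < 0.7
        m[3, 3, 3] = True
        shifted = np.roll(m, (4, 3, 5), axis=(0, 1, 2))
        f1, f2 = shape_features(RoiMask(m, (1, 1, 1))), shape_features(RoiMask(shifted, (1, 1, 1)))
        for key in f1:
            assert f1[key] == pytest.approx(f2[key])

    def test_digitized_ball_converges(self):
        """Voxelized sphere: volume → (4/3)πr³ within 5% by r=20; the
        face-count disproportion stabilizes as the staircase bias saturates."""
        disproportions = []
        for r in (10, 15, 20):
            n = 2 * r + 3
            c = (n - 1) / 2
            g = np.indices((n, n, n))
            ball = ((g[0] - c) ** 2 + (g[1] - c) ** 2 + (g[2] - c) ** 2) <= r**2
            if r == 20:
                assert ball.sum() == pytest.approx(4 / 3 * math.pi * r**3, rel=0.05)
            disproportions.append(shape_features(RoiMask(ball, (1, 1, 1)))["spherical_disproportion"])
        assert abs(disproportions[2] - disproportions[1]) < 0.05 * disproportions[1]


class TestGlcm:
    def test_hand_enumerated_2d_slice(self):
        lv = np.array([[[1], [1]], [[2], [2]]])  # shape (2,2,1)
        mask = np.ones((2, 2, 1), bool)
        g = glcm(lv, mask, offsets=((0, 1, 0),), n_levels=2)
        np.testing.assert_allclose(g.counts, np.diag([0.5, 0.5]))

    def test_constant_roi_single_entry(self):
        lv = np.ones((3, 3, 3), dtype=int)
        g = glcm(lv, np.ones((3, 3, 3), bool), n_levels=4)
        assert g.counts[0, 0] == pytest.approx(1.0)
        assert g.counts.sum() == pytest.approx(1.0)

    def test_too_small_roi_rejected(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        with pytest.raises(ValueError, match="no co-occurrences"):
            glcm(np.ones((3, 3, 3), int), mask, n_levels=2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_random_rois(self, seed):
        rng = np.random.default_rng(seed)
        n_levels = 4
        lv = rng.integers(1, n_levels + 1, size=(5, 5, 5))
        mask = rng.random((5, 5, 5)) < 0.6
        mask[2, 2, 2] = mask[2, 2, 3] = True
        got = glcm(lv, mask, n_levels=n_levels)
        expected = glcm_bruteforce(lv, mask, GLCM_OFFSETS, n_levels)
        np.testing.assert_allclose(got.counts, expected, atol=1e-12)
        np.testing.assert_allclose(got.counts, got.counts.T, atol=1e-12)  # symmetry


class TestGlcmFeatures:
    def test_constant_matrix_degenerate(self):
        lv = np.ones((3, 3, 3), int)
        f = glcm_features(glcm(lv, np.ones((3, 3, 3), bool), n_levels=4))
        assert f["maximum_probability"] == pytest.approx(1.0)
        assert f["cluster_shade"] == pytest.approx(0.0)
        assert math.isnan(f["correlation"])  # zero marginal variance

    def test_level_reversal_symmetry_kills_shade(self, rng):
        n = 6
        p = rng.random((n, n))
        p = p + p.T
        p = p + p[::-1, ::-1]  # symmetric under level reversal
        p /= p.sum()
        from radiopath.radiomic_features import GlcMatrix

        f = glcm_features(GlcMatrix(p, n, (), True))
        assert f["cluster_shade"] == pytest.approx(0.0, abs=1e-12)

    def test_random_matrix_matches_direct_summation(self, rng):
        from radiopath.radiomic_features import GlcMatrix

        n = 8
        p = rng.random((n, n))
        p = (p + p.T) / 2
        p /= p.sum()
        f = glcm_features(GlcMatrix(p, n, (), True))
        i = np.arange(1, n + 1)
        mu = sum(i[a] * p[a, b] for a in range(n) for b in range(n))
        shade = sum((i[a] + i[b] - 2 * mu) ** 3 * p[a, b] for a in range(n) for b in range(n))
        prom = sum((i[a] + i[b] - 2 * mu) ** 4 * p[a, b] for a in range(n) for b in range(n))
        contrast = sum((i[a] - i[b]) ** 2 * p[a, b] for a in range(n) for b in range(n))
        assert f["cluster_shade"] == pytest.approx(shade)
        assert f["cluster_prominence"] == pytest.approx(prom)
        assert f["contrast"] == pytest.approx(contrast)
        assert f["maximum_probability"] == pytest.approx(p.max())

    def test_unnormalized_matrix_rejected(self):
        from radiopath.radiomic_features import GlcMatrix

        with pytest.raises(ValueError, match="normalized"):
            glcm_features(GlcMatrix(np.ones((4, 4)), 4, (), False))


class TestGlszm:
    def test_constant_cube_single_zone(self):
        lv = np.ones((2, 2, 2), int)
        g = glszm(lv, np.ones((2, 2, 2), bool), n_levels=2)
        assert g.n_zones == 1
        assert g.counts[0, 7] == 1  # level 1, size 8

    def test_two_disjoint_voxels_two_zones(self):
        lv = np.ones((5, 5, 5), int)
        mask = np.zeros((5, 5, 5), bool)
        mask[0, 0, 0] = mask[4, 4, 4] = True
        g = glszm(lv, mask, n_levels=2)
        assert g.n_zones == 2
        assert g.counts[0, 0] == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_floodfill_oracle(self, seed):
        rng = np.random.default_rng(seed + 100)
        n_levels = 3
        lv = rng.integers(1, n_levels + 1, size=(6, 6, 6))
        mask = rng.random((6, 6, 6)) < 0.6
        mask[3, 3, 3] = True
        got = glszm(lv, mask, n_levels=n_levels)
        expected = glszm_bruteforce(lv, mask, n_levels)
        np.testing.assert_array_equal(got.counts, expected)


class TestGlszmFeatures:
    def test_single_zone_unit_variabilities(self):
        lv = np.ones((2, 2, 2), int)
        f = glszm_features(glszm(lv, np.ones((2, 2, 2), bool), n_levels=2))
        assert f["size_zone_variability"] == pytest.approx(1.0)
        assert f["intensity_variability"] == pytest.approx(1.0)

    def test_two_same_size_zones_different_levels(self):
        from radiopath.radiomic_features import GlszMatrix

        counts = np.zeros((2, 4))
        counts[0, 2] = counts[1, 2] = 1  # two zones of size 3, levels 1 and 2
        f = glszm_features(GlszMatrix(counts, 2))
        assert f["size_zone_variability"] == pytest.approx(2.0)
        assert f["intensity_variability"] == pytest.approx(1.0)

    def test_random_matrix_matches_direct_summation(self, rng):
        from radiopath.radiomic_features import GlszMatrix

        counts = rng.integers(0, 4, size=(5, 9)).astype(float)
        counts[0, 0] += 1
        f = glszm_features(GlszMatrix(counts, 5))
        N = counts.sum()
        szv = sum(counts[:, s].sum() ** 2 for s in range(9)) / N
        inv = sum(counts[g, :].sum() ** 2 for g in range(5)) / N
        sze = sum(counts[g, s] / (s + 1) ** 2 for g in range(5) for s in range(9)) / N
        assert f["size_zone_variability"] == pytest.approx(szv)
        assert f["intensity_variability"] == pytest.approx(inv)
        assert f["small_zone_emphasis"] == pytest.approx(sze)


class TestExtractAll:
    def test_conformance_52_features_six_categories(self):
        vol, mask = make_tumor_phantom(PhantomSpec(seed=5))
        fv = extract_all(vol, mask)
        assert len(fv.values) == 52
        counts = fv.category_counts()
        assert sum(counts.values()) == 52
        assert set(counts) == {"global", "histogram", "lung_cancer_specific", "shape", "local", "regional"}

    def test_determinism(self):
        vol, mask = make_tumor_phantom(PhantomSpec(seed=7))
        f1 = extract_all(vol, mask).values
        f2 = extract_all(vol, mask).values
        assert f1 == f2

    def test_all_negative_roi_only_mpp_missing(self):
        spec = PhantomSpec(base_hu=-600, texture_sd=20, seed=3)
        vol, mask = make_tumor_phantom(spec)
        fv = extract_all(vol, mask)
        assert math.isnan(fv.values["mpp"])
        others = [v for k, v in fv.values.items() if k != "mpp"]
        assert all(not math.isnan(v) for v in others)

    def test_constant_roi_energy_entropy_duality(self):
        vol, mask = make_tumor_phantom(PhantomSpec(texture_sd=0.0))
        fv = extract_all(vol, mask)
        assert fv.values["energy"] == 1.0
        assert fv.values["entropy"] == 0.0
        # and a textured ROI is strictly less uniform
        vol2, mask2 = make_tumor_phantom(PhantomSpec(texture_sd=60.0, seed=2))
        fv2 = extract_all(vol2, mask2)
        assert fv2.values["energy"] < 1.0
        assert fv2.values["entropy"] > 0.0

    def test_frozen_category_roster(self):
        counts = {}
        for cat in FEATURE_CATEGORIES.values():
            counts[cat] = counts.get(cat, 0) + 1
        assert counts == {
            "global": 2, "histogram": 15, "lung_cancer_specific": 5,
            "shape": 7, "local": 15, "regional": 8,
        }
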