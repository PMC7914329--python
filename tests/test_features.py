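import math

import numpy as np
import pytest

from petrad import DiscretizationSetting, EmptyVOIError, SUVImage, VOIMask, discretize, extract_all
from petrad.discretization import DiscretizedVOI
from petrad.features import (
    ALL_FEATURE_NAMES,
    GLCM_NAMES,
    TEXTURE_NAMES,
    conventional_features,
    glcm_features,
    glcm_matrix,
    glrlm_features,
    glrlm_matrix,
    glzlm_features,
    glzlm_matrix,
    histogram_features,
    ngldm_features,
    shape_features,
    suv_peak,
)

from .conftest import random_disc
from . import oracles

AR60 = DiscretizationSetting()


def _pair(values, mask=None, spacing=4.0):
    values = np.asarray(values, dtype=float)
    img = SUVImage(values, (spacing,) * 3)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    return img, VOIMask(mask, (spacing,) * 3)


def _const_disc(n=27, level=1):
    side = round(n ** (1 / 3))
    mask = np.ones((side, side, side), dtype=bool)
    levels = np.full((side, side, side), level, dtype=np.int64)
    return DiscretizedVOI(levels=levels, mask=mask, n_bins=64, setting=AR60,
                          bin_width=60 / 64, spacing=(4.0,) * 3)


class TestConventional:
    def test_hand_case_1_to_8(self):
        img, mask = _pair(np.arange(1.0, 9.0).reshape(2, 2, 2))
        f = conventional_features(img, mask)
        assert f["CONV_SUVmax"] == 8
        assert f["CONV_SUVmin"] == 1
        assert f["CONV_SUVmean"] == 4.5
        assert f["CONV_SUVQ2"] == 4.5
        # 8 voxels x 0.064 mL; TLSRE = 4.5 * 0.512
        assert f["CONV_TLSRE"] == pytest.approx(4.5 * 0.512)

    def test_constant_voi(self):
        img, mask = _pair(np.full((3, 3, 3), 7.0))
        f = conventional_features(img, mask)
        assert f["CONV_SUVstd"] == 0.0
        for q in ("CONV_SUVQ1", "CONV_SUVQ2", "CONV_SUVQ3"):
            assert f[q] == 7.0

    def test_empty_mask_raises(self):
        img, _ = _pair(np.ones((2, 2, 2)))
        with pytest.raises(EmptyVOIError):
            conventional_features(img, VOIMask(np.zeros((2, 2, 2), bool)))


class TestSUVPeak:
    def test_constant_image(self):
        img, mask = _pair(np.full((7, 7, 7), 4.2))
        assert suv_peak(img, mask, 0.5) == pytest.approx(4.2)
        assert suv_peak(img, mask, 1.0) == pytest.approx(4.2)

    def test_single_hot_voxel_matches_exhaustive_placement(self):
        vals = np.zeros((9, 9, 9))
        vals[4, 4, 4] = 100.0
        img, mask = _pair(vals)
        for vol in (0.5, 1.0):
            ref = oracles.suv_peak_oracle(vals, mask.values, (4.0,) * 3, vol)
            assert suv_peak(img, mask, vol) == pytest.approx(ref, rel=1e-10)

    def test_oracle_equivalence_random(self, rng):
        vals = rng.random((8, 8, 8)) * 30
        m = rng.random((8, 8, 8)) < 0.4
        m[4, 4, 4] = True
        img, mask = _pair(vals, mask=m)
        for vol in (0.5, 1.0):
            ref = oracles.suv_peak_oracle(vals, m, (4.0,) * 3, vol)
            assert suv_peak(img, mask, vol) == pytest.approx(ref, rel=1e-10)

    def test_averaging_monotonicity(self, small_cohort):
        records, _ = small_cohort
        for rec in records:
            p05 = suv_peak(rec.image, rec.truth, 0.5)
            p1 = suv_peak(rec.image, rec.truth, 1.0)
            smax = rec.image.values[rec.truth.values].max()
            assert p1 <= p05 + 1e-12
            assert p05 <= smax + 1e-12


class TestHistogram:
    def test_uniform_over_k_levels(self):
        side = 4
        levels = np.tile(np.arange(1, 5, dtype=np.int64), 16).reshape(side, side, side)
        disc = DiscretizedVOI(levels=levels, mask=np.ones((side,) * 3, bool),
                              n_bins=64, setting=AR60, bin_width=1.0,
                              spacing=(4.0,) * 3)
        f = histogram_features(disc)
        assert f["HISTO_Energy"] == pytest.approx(1 / 4)
        assert f["HISTO_Entropy_log2"] == pytest.approx(2.0)
        assert f["HISTO_Entropy_log10"] == pytest.approx(math.log10(4))

    def test_single_level(self):
        f = histogram_features(_const_disc())
        assert f["HISTO_Energy"] == 1.0
        assert f["HISTO_Entropy_log2"] == 0.0
        assert np.isnan(f["HISTO_Skewness"])
        assert np.isnan(f["HISTO_Kurtosis"])

    def test_moments_match_bruteforce(self, rng):
        disc = random_disc(rng, shape=(6, 6, 6), n_levels=10)
        lev = disc.in_mask_levels.astype(float)
        mu = lev.mean()
        sd = lev.std()
        f = histogram_features(disc)
        assert f["HISTO_Skewness"] == pytest.approx(
            np.mean((lev - mu) ** 3) / sd**3, rel=1e-10)
        # non-excess kurtosis: a normal sample would sit near 3
        assert f["HISTO_Kurtosis"] == pytest.approx(
            np.mean((lev - mu) ** 4) / sd**4, rel=1e-10)


class TestShape:
    def test_single_voxel_volume(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        m[1, 1, 1] = True
        f = shape_features(VOIMask(m, (4.0,) * 3))
        assert f["SHAPE_Volume_mL"] == pytest.approx(0.064)
        assert f["SHAPE_Volume_vox"] == 1

    def test_digital_ball_sphericity_near_one(self):
        n, r = 25, 10
        ax = np.arange(n) - n // 2
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        ball = x**2 + y**2 + z**2 <= r**2
        f = shape_features(VOIMask(ball, (4.0,) * 3))
        assert 0.95 <= f["SHAPE_Sphericity"] <= 1.05

    def test_elongation_monotonicity(self):
        # fixed voxel count, increasing aspect ratio: sphericity falls,
        # compacity rises
        def ellipsoid(a, b):
            n = 41
            ax = np.arange(n) - n // 2
            x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
            return (x / a) ** 2 + (y / b) ** 2 + (z / b) ** 2 <= 1.0

        sph, comp = [], []
        for a, b in [(8, 8), (14, 6.05), (20, 5.1)]:  # roughly equal volumes
            f = shape_features(VOIMask(ellipsoid(a, b), (4.0,) * 3))
            sph.append(f["SHAPE_Sphericity"])
            comp.append(f["SHAPE_Compacity"])
        assert sph[0] > sph[1] > sph[2]
        assert comp[0] < comp[1] < comp[2]


class TestGLCM:
    def test_constant_voi(self):
        f = glcm_features(_const_disc())
        assert f["GLCM_Homogeneity"] == 1.0
        assert f["GLCM_Contrast"] == 0.0
        assert f["GLCM_Dissimilarity"] == 0.0
        assert f["GLCM_Energy"] == 1.0
        assert f["GLCM_Entropy_log2"] == 0.0
        assert np.isnan(f["GLCM_Correlation"])

    def test_matrix_normalized_and_symmetric(self, rng):
        disc = random_disc(rng)
        m = glcm_matrix(disc)
        assert m.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(m, m.T, rtol=1e-12)

    def test_no_valid_pairs_gives_nan(self):
        # two isolated voxels, too far apart for any distance-1 pair
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[0, 0, 0] = mask[4, 4, 4] = True
        levels = np.where(mask, 3, 0).astype(np.int64)
        disc = DiscretizedVOI(levels=levels, mask=mask, n_bins=64, setting=AR60,
                              bin_width=1.0, spacing=(4.0,) * 3)
        f = glcm_features(disc)
        assert all(np.isnan(v) for v in f.values())

    def test_oracle_equivalence(self, rng):
        for _ in range(20):
            disc = random_disc(rng, shape=(3, 3, 2), n_levels=4)
            ref = oracles.glcm_oracle(disc.levels, disc.mask)
            f = glcm_features(disc)
            mapping = {
                "GLCM_Homogeneity": "homogeneity", "GLCM_Energy": "energy",
                "GLCM_Contrast": "contrast", "GLCM_Correlation": "correlation",
                "GLCM_Entropy_log10": "entropy_log10",
                "GLCM_Entropy_log2": "entropy_log2",
                "GLCM_Dissimilarity": "dissimilarity",
            }
            for name, okey in mapping.items():
                np.testing.assert_allclose(
                    f[name], ref[okey], rtol=1e-10, equal_nan=True,
                    err_msg=name)


class TestGLRLM:
    def test_constant_voi_low_level(self):
        f = glrlm_features(_const_disc(level=1))
        assert f["GLRLM_LGRE"] == 1.0
        assert f["GLRLM_HGRE"] == 1.0

    def test_run_conservation(self, rng):
        for _ in range(10):
            disc = random_disc(rng, shape=(5, 4, 3), n_levels=5)
            mat = glrlm_matrix(disc)
            j = np.arange(1, mat.shape[1] + 1)
            assert (mat * j).sum() == pytest.approx(13 * disc.n_voxels)

    def test_oracle_equivalence(self, rng):
        for _ in range(20):
            disc = random_disc(rng, shape=(4, 4, 1), n_levels=4)
            mat = glrlm_matrix(disc)
            ref_mat = oracles.glrlm_counts_oracle(disc.levels, disc.mask)
            np.testing.assert_allclose(mat, ref_mat)
            ref = oracles.run_zone_features_oracle(
                ref_mat, disc.n_voxels, 13 * disc.n_voxels)
            f = glrlm_features(disc)
            for name, okey in [
                ("GLRLM_SRE", "short"), ("GLRLM_LRE", "long"),
                ("GLRLM_LGRE", "lg"), ("GLRLM_HGRE", "hg"),
                ("GLRLM_SRLGE", "sl"), ("GLRLM_SRHGE", "sh"),
                ("GLRLM_LRLGE", "ll"), ("GLRLM_LRHGE", "lh"),
                ("GLRLM_GLNU", "glnu"), ("GLRLM_RLNU", "lnu"),
                ("GLRLM_RP", "pct"),
            ]:
                np.testing.assert_allclose(f[name], ref[okey], rtol=1e-10,
                                           err_msg=name)


class TestGLZLM:
    def test_constant_voi_single_zone(self):
        n = 27
        f = glzlm_features(_const_disc(n=n))
        assert f["GLZLM_ZP"] == pytest.approx(1.0 / n)

    def test_zone_conservation(self, rng):
        for _ in range(10):
            disc = random_disc(rng, shape=(5, 5, 4), n_levels=5)
            mat = glzlm_matrix(disc)
            j = np.arange(1, mat.shape[1] + 1)
            assert (mat * j).sum() == pytest.approx(disc.n_voxels)

    def test_checkerboard_zones_merge_diagonally(self):
        # in-plane checkerboard of two levels: 26-connectivity joins the
        # diagonal neighbours, so each level forms ONE zone (sizes 5 and 4
        # on a 3x3x1 grid), matching the flood-fill oracle
        levels = np.indices((3, 3, 1)).sum(axis=0) % 2 + 1
        disc = DiscretizedVOI(levels=levels.astype(np.int64),
                              mask=np.ones((3, 3, 1), bool), n_bins=64,
                              setting=AR60, bin_width=1.0, spacing=(4.0,) * 3)
        mat = glzlm_matrix(disc)
        ref_mat = oracles.glzlm_counts_oracle(disc.levels, disc.mask)
        np.testing.assert_allclose(mat, ref_mat)
        # level 1 occupies the 5 even-parity cells, level 2 the 4 odd ones
        assert mat[0, 4] == 1 and mat[1, 3] == 1
        assert mat.sum() == 2

    def test_oracle_equivalence(self, rng):
        for _ in range(20):
            disc = random_disc(rng, shape=(4, 4, 3), n_levels=4)
            np.testing.assert_allclose(
                glzlm_matrix(disc),
                oracles.glzlm_counts_oracle(disc.levels, disc.mask))


class TestNGLDM:
    def test_constant_voi_contrast_zero(self):
        f = ngldm_features(_const_disc())
        assert f["NGLDM_Contrast"] == 0.0

    def test_coarseness_positive(self, rng):
        disc = random_disc(rng, shape=(4, 4, 4), n_levels=5)
        f = ngldm_features(disc)
        assert f["NGLDM_Coarseness"] > 0

    def test_isolated_voxels_nan(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[0, 0, 0] = mask[4, 4, 4] = True
        levels = np.where(mask, 2, 0).astype(np.int64)
        disc = DiscretizedVOI(levels=levels, mask=mask, n_bins=64, setting=AR60,
                              bin_width=1.0, spacing=(4.0,) * 3)
        assert all(np.isnan(v) for v in ngldm_features(disc).values())

    def test_oracle_equivalence(self, rng):
        for _ in range(20):
            disc = random_disc(rng, shape=(3, 3, 3), n_levels=4)
            ref = oracles.ngldm_oracle(disc.levels, disc.mask)
            f = ngldm_features(disc)
            np.testing.assert_allclose(f["NGLDM_Coarseness"], ref["coarseness"],
                                       rtol=1e-10, equal_nan=True)
            np.testing.assert_allclose(f["NGLDM_Contrast"], ref["contrast"],
                                       rtol=1e-10, equal_nan=True)
            np.testing.assert_allclose(f["NGLDM_Busyness"], ref["busyness"],
                                       rtol=1e-10, equal_nan=True)


class TestExtractAll:
    def test_exactly_51_named_entries(self, small_cohort):
        records, _ = small_cohort
        rec = records[0]
        f = extract_all(rec.image, rec.truth, AR60)
        assert tuple(f.keys()) == ALL_FEATURE_NAMES
        assert len(f) == 51

    def test_small_voi_textures_nan(self):
        vals = np.zeros((4, 4, 4))
        m = np.zeros((4, 4, 4), dtype=bool)
        m[1, 1, 1:3] = True
        vals[m] = [5.0, 9.0]
        img, mask = _pair(vals, mask=m)
        f = extract_all(img, mask, AR60, min_voxels_texture=8)
        assert not np.isnan(f["CONV_SUVmean"])
        assert not np.isnan(f["SHAPE_Volume_mL"])
        for name in TEXTURE_NAMES:
            assert np.isnan(f[name]), name

    def test_single_gray_level_textures_nan(self):
        img, mask = _pair(np.full((3, 3, 3), 5.0))
        f = extract_all(img, mask, DiscretizationSetting(mode="relative"))
        for name in TEXTURE_NAMES:
            assert np.isnan(f[name]), name

    def test_lifex_zero_fill_flag(self):
        img, mask = _pair(np.arange(27, dtype=float).reshape(3, 3, 3) + 1)
        f = extract_all(img, mask, AR60, lifex_small_voi_zero_fill=True)
        assert f["SHAPE_Sphericity"] == 0.0
        assert f["SHAPE_Compacity"] == 0.0
        g = extract_all(img, mask, AR60)
        assert g["SHAPE_Sphericity"] > 0.0

    def test_conventional_independent_of_discretization(self, small_cohort):
        records, _ = small_cohort
        rec = records[1]
        fa = extract_all(rec.image, rec.truth, AR60)
        fr = extract_all(rec.image, rec.truth, DiscretizationSetting(mode="relative"))
        for name in fa:
            if name.startswith(("CONV_", "SHAPE_")):
                assert fa[name] == fr[name], name

    def test_tlsre_identity(self, small_cohort):
        records, _ = small_cohort
        for rec in records:
            f = extract_all(rec.image, rec.truth, AR60)
            assert f["CONV_TLSRE"] == pytest.approx(
                f["CONV_SUVmean"] * f["SHAPE_Volume_mL"], rel=1e-12)

    def test_texture_matrix_trailing_empty_rows_harmless(self, rng):
        # features summing over gray rows must not change when the level
        # array is embedded among higher unoccupied levels
        disc = random_disc(rng, shape=(4, 4, 4), n_levels=4)
        f1 = glrlm_features(disc)
        mat = glrlm_matrix(disc)
        padded = np.vstack([mat, np.zeros((3, mat.shape[1]))])
        # row-sum features from the padded matrix agree (GLNU etc.)
        total = padded.sum()
        glnu = (padded.sum(axis=1) ** 2).sum() / total
        assert glnu == pytest.approx(f1["GLRLM_GLNU"], rel=1e-12)
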