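"""Texture matrices and features vs hand fixtures and brute-force oracles."""

import numpy as np
import pytest

from fetrad.features import (
    FEATURE_NAMES,
    FeatureExtractor,
    histogram_features,
    shape_features,
)
from fetrad.images import SUVImage, sphere_mask
from fetrad.texture import (
    GLSZM,
    NGTDM,
    build_glcm,
    build_glrlm,
    build_glszm,
    build_ngtdm,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_busyness,
    ngtdm_features,
    ngtdm_strength,
    szlge,
)

from conftest import image_from, make_disc, random_roi
from oracles import (
    brute_busyness_strength,
    brute_glcm,
    brute_glrlm,
    brute_glszm,
    brute_glszm_features,
    brute_ngtdm,
)

# the 3x3x1 plane with three same-size zones, one per level
THREE_ZONE_PLANE = [[1, 1, 2], [1, 2, 2], [3, 3, 3]]


class TestGLCM:
    def test_single_pair(self):
        g = build_glcm(make_disc([[1], [2]]))
        assert g.p[0, 1] == 0.5 and g.p[1, 0] == 0.5
        assert g.p.sum() == 1.0

    def test_constant_roi(self):
        g = build_glcm(make_disc(np.ones((2, 2, 2), int)))
        assert g.p[0, 0] == 1.0

    def test_matches_bruteforce(self, rng):
        for _ in range(25):
            disc, ng = random_roi(rng)
            got = build_glcm(disc).p
            lv, m = disc.levels, disc.mask
            want = brute_glcm(lv, m, ng)
            np.testing.assert_allclose(got, want, rtol=0, atol=1e-12)

    def test_symmetric_and_normalized(self, rng):
        disc, _ = random_roi(rng, max_side=5)
        g = build_glcm(disc)
        if g.n_pairs:
            np.testing.assert_allclose(g.p, g.p.T)
            assert g.p.sum() == pytest.approx(1.0)


class TestGLRLM:
    def test_rod_runs(self):
        r = build_glrlm(make_disc(np.ones((1, 1, 3), int)))
        # one direction sees a single run of 3; the other 12 see runs of 1
        counts = r.counts
        assert counts[0, 2] == 1
        assert counts[0, 0] == 12 * 3
        assert r.n_runs == 37

    def test_constant_cube_runs_partition_voxels_per_direction(self):
        disc = make_disc(np.ones((2, 2, 2), int))
        r = build_glrlm(disc)
        # every direction's runs must cover all 8 voxels
        assert (r.counts * np.arange(1, r.counts.shape[1] + 1)).sum() == 8 * 13

    def test_all_distinct_levels_gives_unit_runs(self):
        lv = np.arange(1, 9).reshape(2, 2, 2)
        r = build_glrlm(make_disc(lv))
        assert r.counts[:, 1:].sum() == 0
        assert r.counts[:, 0].sum() == 13 * 8

    def test_matches_bruteforce(self, rng):
        for _ in range(25):
            disc, ng = random_roi(rng)
            got = build_glrlm(disc).counts
            want = brute_glrlm(disc.levels, disc.mask, ng)
            assert np.array_equal(got[:, : want.shape[1]], want[:, : got.shape[1]])
            assert got.sum() == want.sum()


class TestGLSZM:
    def test_constant_cube_single_zone(self):
        z = build_glszm(make_disc(np.ones((2, 2, 2), int)))
        assert z.n_zones == 1
        assert z.counts[0, 7] == 1

    def test_three_zone_plane(self):
        z = build_glszm(make_disc(THREE_ZONE_PLANE))
        assert z.n_zones == 3
        for lvl in (1, 2, 3):
            assert z.counts[lvl - 1, 2] == 1  # one zone of size 3 per level

    def test_checkerboard_under_6_connectivity(self):
        idx = np.indices((4, 4, 4)).sum(axis=0)
        lv = idx % 2 + 1
        z = build_glszm(make_disc(lv), connectivity=6)
        assert z.n_zones == 64  # every voxel its own zone

    def test_mass_conservation(self, rng):
        for _ in range(20):
            disc, _ = random_roi(rng)
            z = build_glszm(disc)
            sizes = np.arange(1, z.counts.shape[1] + 1)
            assert (z.counts * sizes).sum() == disc.mask.sum()

    def test_matches_bruteforce(self, rng):
        for _ in range(25):
            disc, ng = random_roi(rng)
            got = build_glszm(disc).counts
            want = brute_glszm(disc.levels, disc.mask, ng)
            w = min(got.shape[1], want.shape[1])
            assert np.array_equal(got[:, :w], want[:, :w])
            assert got.sum() == want.sum()


class TestNGTDM:
    def test_constant_roi_zero_differences(self):
        t = build_ngtdm(make_disc(np.ones((3, 3, 3), int)))
        assert np.all(t.s_i == 0)

    def test_two_voxel_fixture(self):
        t = build_ngtdm(make_disc([[1], [3]]))
        assert t.s_i[0] == pytest.approx(2.0)
        assert t.s_i[2] == pytest.approx(2.0)
        assert t.p_i[0] == t.p_i[2] == 0.5

    def test_matches_bruteforce(self, rng):
        for _ in range(25):
            disc, ng = random_roi(rng)
            t = build_ngtdm(disc)
            p_want, s_want = brute_ngtdm(disc.levels, disc.mask, ng)
            np.testing.assert_allclose(t.p_i, p_want, atol=1e-12)
            np.testing.assert_allclose(t.s_i, s_want, atol=1e-10)


class TestDerivedFeatures:
    def test_szlge_uniform_cube(self):
        z = build_glszm(make_disc(np.ones((2, 2, 2), int)))
        assert szlge(z) == pytest.approx(1.0 / 64.0)

    def test_szlge_three_zone_plane(self):
        z = build_glszm(make_disc(THREE_ZONE_PLANE))
        want = (1 / 3) * (1 / 9 + 1 / 36 + 1 / 81)
        assert szlge(z) == pytest.approx(want)

    def test_szlge_decreases_under_level_doubling(self):
        z1 = build_glszm(make_disc(THREE_ZONE_PLANE))
        z2 = build_glszm(make_disc(2 * np.asarray(THREE_ZONE_PLANE)))
        assert szlge(z2) < szlge(z1)

    def test_hgze_increases_under_level_shift(self):
        z1 = build_glszm(make_disc(THREE_ZONE_PLANE))
        z2 = build_glszm(make_disc(np.asarray(THREE_ZONE_PLANE) + 3))
        assert glszm_features(z2)["HGZE"] > glszm_features(z1)["HGZE"]

    def test_hgze_three_zone_plane(self):
        z = build_glszm(make_disc(THREE_ZONE_PLANE))
        assert glszm_features(z)["HGZE"] == pytest.approx(14.0 / 3.0)

    def test_single_zone_closed_forms(self):
        z = build_glszm(make_disc(np.ones((2, 2, 2), int)))
        f = glszm_features(z)
        assert f["HGZE"] == 1.0
        assert f["GLN2"] == 1.0

    def test_gln2_bounded_in_unit_interval(self, rng):
        for _ in range(15):
            disc, _ = random_roi(rng)
            f = glszm_features(build_glszm(disc))
            assert 0 < f["GLN2"] <= 1.0

    def test_busyness_two_voxel_fixture(self):
        t = build_ngtdm(make_disc([[1], [3]]))
        assert ngtdm_busyness(t) == pytest.approx(1.0)

    def test_busyness_strength_undefined_for_constant_roi(self):
        t = build_ngtdm(make_disc(np.ones((2, 2, 2), int)))
        assert np.isnan(ngtdm_busyness(t))
        assert np.isnan(ngtdm_strength(t))

    def test_strength_nonnegative(self, rng):
        for _ in range(15):
            disc, _ = random_roi(rng)
            s = ngtdm_strength(build_ngtdm(disc))
            assert np.isnan(s) or s >= 0

    def test_glcm_point_mass_and_two_level(self):
        g = build_glcm(make_disc(np.ones((2, 1, 1), int)))
        f = glcm_features(g)
        assert f["Acor"] == 1.0 and f["Variance_CM"] == 0.0
        g2 = build_glcm(make_disc([[1], [2]]))
        f2 = glcm_features(g2)
        assert f2["Acor"] == pytest.approx(2.0)
        assert f2["Variance_CM"] == pytest.approx(0.25)

    def test_glrlm_single_run_closed_forms(self):
        lv = np.full((1, 1, 3), 2, dtype=int)
        r = build_glrlm(make_disc(lv))
        # pick out the run of length 3 along the rod axis by direct formula
        # on a matrix holding only that run
        from fetrad.texture import GLRLM

        counts = np.zeros((2, 3), dtype=np.int64)
        counts[1, 2] = 1
        f = glrlm_features(GLRLM(counts, 2, 1, 3))
        assert f["HGRE"] == pytest.approx(4.0)
        assert f["SRHGE"] == pytest.approx(4.0 / 9.0)
        assert f["LRHGE"] == pytest.approx(36.0)
        assert f["GLV"] == 0.0

    def test_glrlm_two_run_variance(self):
        from fetrad.texture import GLRLM

        counts = np.zeros((3, 1), dtype=np.int64)
        counts[0, 0] = counts[2, 0] = 1
        f = glrlm_features(GLRLM(counts, 3, 2, 2))
        assert f["GLV"] == pytest.approx(1.0)

    def test_glszm_features_match_literal_sums(self, rng):
        for _ in range(15):
            disc, _ = random_roi(rng)
            z = build_glszm(disc)
            want = brute_glszm_features(z.counts)
            got = glszm_features(z)
            for k, v in want.items():
                assert got[k] == pytest.approx(v, rel=1e-12)

    def test_ngtdm_features_match_literal_sums(self, rng):
        for _ in range(15):
            disc, _ = random_roi(rng)
            t = build_ngtdm(disc)
            busy, strength = brute_busyness_strength(t.p_i, t.s_i)
            np.testing.assert_allclose(ngtdm_busyness(t), busy, rtol=1e-12)
            np.testing.assert_allclose(ngtdm_strength(t), strength, rtol=1e-12)


class TestHistogramShape:
    def test_constant_roi(self):
        img = image_from(np.full((2, 2, 2), 2.0))
        f = histogram_features(img, np.ones((2, 2, 2), bool))
        assert f["SUV_min"] == f["SUV_max"] == f["SUV_mean"] == 2.0
        assert f["Variance"] == 0.0

    def test_population_variance(self):
        img = image_from([1.0, 2.0, 3.0])
        f = histogram_features(img, np.ones(img.shape, bool))
        assert f["SUV_mean"] == 2.0
        assert f["Variance"] == pytest.approx(2.0 / 3.0)

    def test_normal_sample_moments(self, rng):
        vals = rng.normal(5.0, 1.0, (12, 12, 12))
        vals = np.abs(vals)
        img = image_from(vals)
        f = histogram_features(img, np.ones(vals.shape, bool))
        n = vals.size
        assert abs(f["Skewness"]) < 3 * np.sqrt(6.0 / n) + 0.02
        assert abs(f["Kurtosis"]) < 3 * np.sqrt(24.0 / n) + 0.05

    def test_rod_is_eccentric_ball_is_not(self):
        rod = np.zeros((11, 3, 3), bool)
        rod[1:10, 1, 1] = True
        f_rod = shape_features(rod, (2, 2, 2))
        assert f_rod["Eccentricity"] > 0.99
        ball = sphere_mask((40, 40, 40), (20, 20, 20), 16.0, (2, 2, 2))
        f_ball = shape_features(ball, (2, 2, 2))
        assert f_ball["Eccentricity"] < 0.2
        assert f_ball["Sphericity"] == pytest.approx(1.0, abs=0.35)

    def test_sphere_volume_recovered(self):
        ball = sphere_mask((24, 24, 24), (12, 12, 12), 10.0, (2, 2, 2))
        f = shape_features(ball, (2, 2, 2))
        assert f["Volume_cc"] == pytest.approx(4.19, rel=0.05)

    def test_single_voxel_axis_features_undefined(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        f = shape_features(m, (2, 2, 2))
        assert np.isnan(f["Eccentricity"]) and np.isnan(f["Elongation"])


@pytest.fixture(scope="module")
def lesion_pair():
    rng = np.random.default_rng(5)
    vals = rng.uniform(1.0, 3.0, (10, 10, 10))
    img = SUVImage(vals, (2, 2, 2))
    mask = sphere_mask((10, 10, 10), (5, 5, 5), 7.0, (2, 2, 2))
    return img, mask


class TestFeatureVector:
    def test_exactly_135_names_in_catalogue_order(self, lesion_pair):
        img, mask = lesion_pair
        vec = FeatureExtractor().extract(img, mask)
        assert tuple(vec) == FEATURE_NAMES
        assert len(vec) == 135

    def test_table_names_present(self):
        for name in ("SUV_min", "SUV_mean", "SZLGE", "Busyness", "WF_TS",
                     "QVariance_CM", "Eccentricity", "GLV", "GLV2", "WF_GLV",
                     "QAcor", "QHGZE", "QSZHGE", "QGLN2", "QHGRE", "QSRHGE",
                     "QLRHGE"):
            assert name in FEATURE_NAMES

    def test_pure_function(self, lesion_pair):
        img, mask = lesion_pair
        a = FeatureExtractor().extract(img, mask)
        b = FeatureExtractor().extract(img, mask)
        assert a == b

    def test_all_entries_finite_or_nan(self, lesion_pair):
        img, mask = lesion_pair
        vec = FeatureExtractor().extract(img, mask)
        for name, v in vec.items():
            assert np.isfinite(v) or np.isnan(v), name

    def test_degenerate_roi_flags_not_drops(self):
        img = image_from(np.full((4, 4, 4), 1.5))
        mask = np.zeros((4, 4, 4), bool)
        mask[1, 1, 1] = True
        vec = FeatureExtractor().extract(img, mask)
        assert len(vec) == 135
        assert np.isnan(vec["Busyness"])
        assert vec["SUV_mean"] == 1.5

    def test_axis_permutation_invariance_isotropic(self, lesion_pair):
        img, mask = lesion_pair
        base = FeatureExtractor().extract(img, mask)
        perm_img = SUVImage(np.transpose(img.values, (2, 0, 1)), img.spacing)
        perm_mask = np.transpose(mask, (2, 0, 1))
        perm = FeatureExtractor().extract(perm_img, perm_mask)
        for name in FEATURE_NAMES:
            np.testing.assert_allclose(
                perm[name], base[name], rtol=1e-9, err_msg=name, equal_nan=True
            )
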