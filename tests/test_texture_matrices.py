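import numpy as np
import pytest

from conftest import levelmap_from_array, random_levelmap
from _oracles import (
    oracle_glcm,
    oracle_gldm,
    oracle_glrlm,
    oracle_glszm,
    oracle_ngtdm,
)
from pancradiomics.io_preprocess import ValidationError
from pancradiomics.texture_matrices import (
    ANGLES,
    GLCM_FEATURES,
    GLDM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
    NGTDM_FEATURES,
    GLCMatrix,
    GLDMatrix,
    TextureParams,
    average_feature_maps,
    compute_glcm,
    compute_gldm,
    compute_glrlm,
    compute_glszm,
    compute_ngtdm,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)


class TestTextureParams:
    @pytest.mark.parametrize("kernel", [0, 6])
    def test_kernel_bounds(self, kernel):
        with pytest.raises(ValidationError):
            TextureParams(bin_count=8, kernel=kernel)

    def test_angles_must_be_known(self):
        with pytest.raises(ValidationError):
            TextureParams(bin_count=8, angles=(30,))


class TestGLCM:
    def test_two_by_two_horizontal_pairs(self):
        lm = levelmap_from_array([[1, 2], [1, 2]])
        m = compute_glcm(lm, TextureParams(bin_count=2), angle=0, distance=1)
        expected = np.array([[0, 2], [2, 0]])
        np.testing.assert_array_equal(m.counts, expected)

    def test_constant_roi_all_diagonal(self):
        lm = levelmap_from_array(np.full((3, 3), 2))
        m = compute_glcm(lm, TextureParams(bin_count=2), angle=0)
        off_diag = m.counts - np.diag(np.diag(m.counts))
        assert off_diag.sum() == 0 and m.total > 0

    def test_total_is_twice_ordered_pairs(self, rng):
        lm = random_levelmap(rng)
        for angle in ANGLES:
            m = compute_glcm(lm, TextureParams(bin_count=4, kernel=2), angle, 2)
            raw = oracle_glcm(lm.levels, 4, angle, 2)
            assert m.total == raw.sum() == 2 * (raw.sum() // 2)

    def test_opposite_offset_gives_same_matrix(self, rng):
        """Symmetric accumulation: angle theta equals theta + 180 degrees."""
        lm = random_levelmap(rng)
        params = TextureParams(bin_count=4)
        for angle, (dy, dx) in ANGLES.items():
            m = compute_glcm(lm, params, angle)
            flipped = oracle_glcm(lm.levels[:, ::-1, ::-1], 4, angle, 1)
            np.testing.assert_array_equal(m.counts, flipped)

    def test_degenerate_single_voxel(self):
        lm = levelmap_from_array([[1]])
        m = compute_glcm(lm, TextureParams(bin_count=2), angle=0)
        assert m.degenerate
        assert all(np.isnan(v) for v in glcm_features(m).values())


class TestGLCMFeatures:
    def test_exactly_twenty_features(self):
        assert len(GLCM_FEATURES) == 20
        lm = levelmap_from_array([[1, 2], [2, 1]])
        feats = glcm_features(compute_glcm(lm, TextureParams(bin_count=2), 0))
        assert tuple(feats) == GLCM_FEATURES

    def test_uniform_two_level_contrast(self):
        m = GLCMatrix(np.ones((2, 2), dtype=np.int64), 2)
        assert glcm_features(m)["contrast"] == pytest.approx(0.5)

    def test_single_entry_energy_and_entropy(self):
        counts = np.zeros((2, 2), dtype=np.int64)
        counts[0, 0] = 4
        feats = glcm_features(GLCMatrix(counts, 2))
        assert feats["joint_energy"] == pytest.approx(1.0)
        assert feats["joint_entropy"] == pytest.approx(0.0)
        assert feats["contrast"] == pytest.approx(0.0)

    def test_bespoke_features_hand_values(self):
        # p = [[0.5, 0.25], [0.25, 0]]; complement c = max(p)-p = [[0,.25],[.25,.5]]
        counts = np.array([[2, 1], [1, 0]], dtype=np.int64)
        feats = glcm_features(GLCMatrix(counts, 2))
        # complement normalized: [[0,.25],[.25,.5]]; mu_x' = mu_y' = 1.75
        # inverse cluster tendency = .25*(3-3.5)^2*2 + .5*(4-3.5)^2 = 0.25
        assert feats["inverse_cluster_tendency"] == pytest.approx(0.25)
        assert feats["inverse_cluster_shade"] == pytest.approx(
            0.25 * (-0.5) ** 3 * 2 + 0.5 * 0.5**3
        )
        # sigma = 0.5; exp(-(1)^2/(2*0.25)) = exp(-2)
        g = np.exp(-2.0)
        # lower triangle (i>=j): p11=0.5 (diff 0), p21=0.25 (diff 1)
        assert feats["gaussian_left_polar"] == pytest.approx(0.5 + 0.25 * g)
        assert feats["inverse_gaussian_left_polar"] == pytest.approx(0.25 * (1 - g))

    def test_uniform_matrix_complement_undefined(self):
        feats = glcm_features(GLCMatrix(np.ones((2, 2), dtype=np.int64), 2))
        assert np.isnan(feats["inverse_cluster_shade"])
        assert np.isnan(feats["inverse_cluster_tendency"])


class TestGLRLM:
    def test_hand_run_decomposition(self):
        lm = levelmap_from_array([[1, 1, 2, 2, 2]])
        m = compute_glrlm(lm, 0)
        assert m.counts[0, 1] == 1  # level 1, length 2
        assert m.counts[1, 2] == 1  # level 2, length 3
        assert m.counts.sum() == 2

    def test_constant_row_single_run(self):
        lm = levelmap_from_array([[3] * 7])
        m = compute_glrlm(lm, 0)
        assert m.counts[2, 6] == 1 and m.counts.sum() == 1

    def test_out_of_roi_breaks_runs(self):
        lm = levelmap_from_array([[1, 1, 0, 1, 1]])
        m = compute_glrlm(lm, 0)
        assert m.counts[0, 1] == 2

    def test_run_percentage(self):
        lm = levelmap_from_array([[1, 1, 2, 2, 2]])
        feats = glrlm_features(compute_glrlm(lm, 0))
        assert feats["run_percentage"] == pytest.approx(0.4)

    def test_all_singleton_runs(self):
        lm = levelmap_from_array([[1, 2, 1, 2]])
        feats = glrlm_features(compute_glrlm(lm, 0))
        assert feats["run_percentage"] == pytest.approx(1.0)
        assert feats["short_run_emphasis"] == pytest.approx(1.0)

    def test_single_run_short_run_emphasis(self):
        lm = levelmap_from_array([[2] * 5])
        feats = glrlm_features(compute_glrlm(lm, 0))
        assert feats["short_run_emphasis"] == pytest.approx(1 / 25)

    def test_exactly_fifteen_features(self):
        assert len(GLRLM_FEATURES) == 15
        lm = levelmap_from_array([[1, 2], [2, 1]])
        assert tuple(glrlm_features(compute_glrlm(lm, 0))) == GLRLM_FEATURES


class TestGLSZM:
    def test_two_disjoint_zones(self):
        arr = np.zeros((1, 3, 9), dtype=np.int16)
        arr[0, 1, 0:3] = 2
        arr[0, 1, 6:9] = 2
        lm = levelmap_from_array(arr)
        m = compute_glszm(lm)
        assert m.counts[1, 2] == 2

    def test_constant_roi_one_zone(self):
        lm = levelmap_from_array(np.full((2, 3, 3), 1))
        m = compute_glszm(lm)
        assert m.counts[0, 17] == 1 and m.counts.sum() == 1
        feats = glszm_features(m)
        assert feats["zone_percentage"] == pytest.approx(1 / 18)
        assert feats["zone_variance"] == pytest.approx(0.0)

    def test_all_singleton_zones(self):
        # all-distinct levels: every voxel is its own zone even at
        # 26-connectivity
        lm = levelmap_from_array([[1, 2, 3], [4, 5, 6]])
        feats = glszm_features(compute_glszm(lm))
        assert feats["zone_percentage"] == pytest.approx(1.0)

    def test_zones_connect_across_slices(self):
        arr = np.zeros((2, 2, 2), dtype=np.int16)
        arr[0, 0, 0] = 1
        arr[1, 1, 1] = 1  # 26-connected diagonal neighbor
        m = compute_glszm(levelmap_from_array(arr))
        assert m.counts[0, 1] == 1

    def test_exactly_fourteen_features(self):
        assert len(GLSZM_FEATURES) == 14
        lm = levelmap_from_array([[1, 2], [2, 1]])
        assert tuple(glszm_features(compute_glszm(lm))) == GLSZM_FEATURES


class TestGLDM:
    def test_constant_three_by_three_center_dependence(self):
        lm = levelmap_from_array(np.full((3, 3), 1))
        m = compute_gldm(lm, TextureParams(bin_count=2, kernel=1))
        # center voxel has 8 matching neighbors; corners 3; edges 5
        assert m.counts[0, 8] == 1
        assert m.counts[0, 3] == 4
        assert m.counts[0, 5] == 4

    def test_isolated_voxel_dependence_zero(self):
        lm = levelmap_from_array([[1]])
        m = compute_gldm(lm, TextureParams(bin_count=2, kernel=1))
        assert m.counts[0, 0] == 1

    def test_two_entry_emphasis_hand_values(self):
        counts = np.zeros((2, 4), dtype=np.int64)
        counts[0, 1] = 1  # dependence 1 -> weight 2
        counts[0, 3] = 1  # dependence 3 -> weight 4
        feats = gldm_features(GLDMatrix(counts, 2))
        assert feats["small_dependence_emphasis"] == pytest.approx((1 / 4 + 1 / 16) / 2)
        assert feats["large_dependence_emphasis"] == pytest.approx((4 + 16) / 2)

    def test_all_dependence_zero_maximal_sde(self):
        counts = np.zeros((2, 1), dtype=np.int64)
        counts[0, 0] = 5
        feats = gldm_features(GLDMatrix(counts, 2))
        assert feats["small_dependence_emphasis"] == pytest.approx(1.0)
        assert feats["dependence_variance"] == pytest.approx(0.0)

    def test_exactly_twelve_features(self):
        assert len(GLDM_FEATURES) == 12
        lm = levelmap_from_array([[1, 2], [2, 1]])
        m = compute_gldm(lm, TextureParams(bin_count=2, kernel=1))
        assert tuple(gldm_features(m)) == GLDM_FEATURES


class TestNGTDM:
    def test_constant_roi_degenerate(self):
        lm = levelmap_from_array(np.full((3, 3), 1))
        feats = ngtdm_features(lm, TextureParams(bin_count=2, kernel=1))
        assert feats["busyness"] == 0.0
        assert feats["complexity"] == 0.0
        assert feats["coarseness"] == pytest.approx(1e6)  # capped sentinel

    def test_checkerboard_matches_oracle(self):
        arr = np.indices((1, 4, 4)).sum(axis=0) % 2 + 1
        lm = levelmap_from_array(arr)
        params = TextureParams(bin_count=2, kernel=1)
        stats = compute_ngtdm(lm, params)
        lv, p, s, n = oracle_ngtdm(lm.levels, 2, 1)
        np.testing.assert_array_equal(stats.levels, lv)
        np.testing.assert_allclose(stats.p, p)
        np.testing.assert_allclose(stats.s, s)
        assert stats.n_valid == n

    def test_exactly_five_features(self):
        assert len(NGTDM_FEATURES) == 5
        lm = levelmap_from_array([[1, 2], [2, 1]])
        assert tuple(ngtdm_features(lm, TextureParams(bin_count=2))) == NGTDM_FEATURES


class TestOracleEquivalence:
    """Randomized cross-check of all five constructors against brute force."""

    N_INSTANCES = 50

    def _instances(self):
        rng = np.random.default_rng(12345)
        for _ in range(self.N_INSTANCES):
            b = int(rng.choice([2, 4, 8]))
            shape = (int(rng.integers(1, 4)), int(rng.integers(2, 7)), int(rng.integers(2, 7)))
            yield rng, random_levelmap(rng, shape=shape, bin_count=b, roi_density=0.75)

    def test_glcm_glrlm_match_oracle(self):
        for rng, lm in self._instances():
            b = lm.bin_count
            angle = int(rng.choice(list(ANGLES)))
            m = compute_glcm(lm, TextureParams(bin_count=b, kernel=2), angle, 1)
            np.testing.assert_array_equal(m.counts, oracle_glcm(lm.levels, b, angle, 1))
            r = compute_glrlm(lm, angle)
            o = oracle_glrlm(lm.levels, b, angle)
            w = max(r.counts.shape[1], o.shape[1])
            np.testing.assert_array_equal(
                np.pad(r.counts, ((0, 0), (0, w - r.counts.shape[1]))),
                np.pad(o, ((0, 0), (0, w - o.shape[1]))),
            )

    def test_glszm_gldm_ngtdm_match_oracle(self):
        for rng, lm in self._instances():
            b = lm.bin_count
            z = compute_glszm(lm)
            oz = oracle_glszm(lm.levels, b)
            w = max(z.counts.shape[1], oz.shape[1])
            np.testing.assert_array_equal(
                np.pad(z.counts, ((0, 0), (0, w - z.counts.shape[1]))),
                np.pad(oz, ((0, 0), (0, w - oz.shape[1]))),
            )
            k = int(rng.integers(1, 4))
            d = compute_gldm(lm, TextureParams(bin_count=b, kernel=k))
            od = oracle_gldm(lm.levels, b, k)
            w = max(d.counts.shape[1], od.shape[1])
            np.testing.assert_array_equal(
                np.pad(d.counts, ((0, 0), (0, w - d.counts.shape[1]))),
                np.pad(od, ((0, 0), (0, w - od.shape[1]))),
            )
            stats = compute_ngtdm(lm, TextureParams(bin_count=b, kernel=k))
            lv, p, s, n = oracle_ngtdm(lm.levels, b, k)
            np.testing.assert_array_equal(stats.levels, lv)
            np.testing.assert_allclose(stats.p, p, atol=1e-12)
            np.testing.assert_allclose(stats.s, s, atol=1e-9)

    def test_conservation_invariants(self):
        for rng, lm in self._instances():
            n = lm.n_voxels
            for angle in ANGLES:
                r = compute_glrlm(lm, angle)
                j = np.arange(1, r.counts.shape[1] + 1)
                assert (r.counts * j[None, :]).sum() == n
            z = compute_glszm(lm)
            s = np.arange(1, z.counts.shape[1] + 1)
            assert (z.counts * s[None, :]).sum() == n
            d = compute_gldm(lm, TextureParams(bin_count=lm.bin_count, kernel=1))
            assert d.counts.sum() == n


class TestInvariances:
    def test_translation_invariance(self, rng):
        lm = random_levelmap(rng, shape=(2, 5, 5), bin_count=4)
        shifted = np.zeros((2, 9, 9), dtype=np.int16)
        shifted[:, 3:8, 2:7] = lm.levels
        lm2 = levelmap_from_array(shifted, bin_count=4)
        params = TextureParams(bin_count=4, kernel=2)
        f1 = glcm_features(compute_glcm(lm, params, 45, 2))
        f2 = glcm_features(compute_glcm(lm2, params, 45, 2))
        for k in f1:
            np.testing.assert_allclose(f1[k], f2[k], equal_nan=True)
        np.testing.assert_allclose(
            list(ngtdm_features(lm, params).values()),
            list(ngtdm_features(lm2, params).values()),
        )

    def test_average_feature_maps(self):
        maps = [{"a": 1.0, "b": 2.0}, {"a": 3.0, "b": 4.0}]
        assert average_feature_maps(maps) == {"a": 2.0, "b": 3.0}
        with pytest.raises(ValidationError):
            average_feature_maps([{"a": 1.0}, {"b": 1.0}])
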