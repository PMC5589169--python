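"""Texture descriptors: first-order moments, GLCM, rotation-invariant co-occurrence LBP."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from rbcfluidity import texture_features as tf
from rbcfluidity.errors import (
    ConfigurationError,
    DegenerateInputError,
    ShapeMismatchError,
)
from rbcfluidity.gp_imaging import BLUE_BAND, GREEN_BAND, ChannelImage


class TestFirstOrder:
    def test_constant_image_degenerate_distribution(self):
        fv = tf.first_order_features(np.full((8, 8), 7.0))
        d = dict(zip(fv.names, fv.values))
        assert d["fo_variance"] == 0.0
        assert d["fo_skewness"] == 0.0
        assert d["fo_kurtosis"] == 0.0
        assert d["fo_energy"] == 1.0
        assert d["fo_entropy"] == 0.0

    def test_bernoulli_half_half(self):
        img = np.zeros((4, 4))
        img[:2] = 1.0
        d = dict(zip(*[tf.first_order_features(img).names, tf.first_order_features(img).values]))
        assert d["fo_mean"] == pytest.approx(0.5)
        assert d["fo_variance"] == pytest.approx(0.25)
        assert d["fo_entropy"] == pytest.approx(1.0)  # one bit
        assert d["fo_energy"] == pytest.approx(0.5)

    def test_matches_direct_summation_oracle(self, rng):
        img = rng.uniform(0, 100, (16, 16))
        fv = tf.first_order_features(img)
        d = dict(zip(fv.names, fv.values))
        vals = img.ravel()
        mean = sum(vals) / vals.size
        var = sum((v - mean) ** 2 for v in vals) / vals.size
        skew = (sum((v - mean) ** 3 for v in vals) / vals.size) / var**1.5
        kurt = (sum((v - mean) ** 4 for v in vals) / vals.size) / var**2 - 3.0
        assert d["fo_mean"] == pytest.approx(mean, abs=1e-10)
        assert d["fo_variance"] == pytest.approx(var, abs=1e-10)
        assert d["fo_skewness"] == pytest.approx(skew, abs=1e-10)
        assert d["fo_kurtosis"] == pytest.approx(kurt, abs=1e-10)

    def test_empty_mask_rejected(self):
        with pytest.raises(DegenerateInputError):
            tf.first_order_features(np.ones((4, 4)), np.zeros((4, 4), bool))


class TestGLCM:
    def test_constant_image_single_cell_matrix(self):
        fv = tf.glcm_features(np.full((8, 8), 3.0))
        d = dict(zip(fv.names, fv.values))
        assert d["glcm_contrast"] == 0.0
        assert d["glcm_energy"] == 1.0
        assert d["glcm_homogeneity"] == 1.0

    def test_checkerboard_hand_enumerated(self):
        board = np.indices((8, 8)).sum(axis=0) % 2
        cfg = tf.GLCMConfig(n_levels=2, offsets=((0, 1),))
        fv = tf.glcm_features(board.astype(float), None, cfg)
        d = dict(zip(fv.names, fv.values))
        # every horizontal neighbour pair is (0,1) or (1,0): P = [[0,.5],[.5,0]]
        assert d["glcm_contrast"] == pytest.approx(1.0)
        assert d["glcm_energy"] == pytest.approx(0.5)
        assert d["glcm_homogeneity"] == pytest.approx(0.5)

    def test_matrix_normalized_and_symmetric(self, rng):
        img = rng.uniform(0, 50, (20, 20))
        mask = rng.random((20, 20)) < 0.7
        cfg = tf.GLCMConfig(n_levels=8)
        for offset in cfg.offsets:
            mat = tf.glcm_matrix(img, mask, cfg, offset)
            assert mat.sum() == pytest.approx(1.0)
            np.testing.assert_allclose(mat, mat.T)

    def test_full_frame_matches_skimage_oracle(self, rng):
        from skimage.feature import graycomatrix, graycoprops

        q = rng.integers(0, 8, (24, 24))
        cfg = tf.GLCMConfig(n_levels=8, offsets=((0, 1),))
        fv = tf.glcm_features(q.astype(float), None, cfg)
        d = dict(zip(fv.names, fv.values))
        P = graycomatrix(q.astype(np.uint8), [1], [0], levels=8, symmetric=True, normed=True)
        p = P[:, :, 0, 0]
        assert d["glcm_contrast"] == pytest.approx(graycoprops(P, "contrast")[0, 0], abs=1e-10)
        assert d["glcm_correlation"] == pytest.approx(
            graycoprops(P, "correlation")[0, 0], abs=1e-10
        )
        assert d["glcm_energy"] == pytest.approx(graycoprops(P, "ASM")[0, 0], abs=1e-10)
        i, j = np.indices(p.shape)
        assert d["glcm_homogeneity"] == pytest.approx(
            np.sum(p / (1.0 + np.abs(i - j))), abs=1e-10
        )
        nz = p[p > 0]
        assert d["glcm_entropy"] == pytest.approx(-np.sum(nz * np.log2(nz)), abs=1e-10)

    def test_feature_ranges(self, rng):
        img = rng.uniform(0, 1, (16, 16))
        d = dict(zip(*[tf.glcm_features(img).names, tf.glcm_features(img).values]))
        assert 0 < d["glcm_energy"] <= 1
        assert 0 < d["glcm_homogeneity"] <= 1
        assert d["glcm_contrast"] >= 0

    def test_no_valid_pairs_rejected(self):
        mask = np.zeros((8, 8), bool)
        mask[0, 0] = True  # a single pixel forms no pair at any offset
        with pytest.raises(DegenerateInputError):
            tf.glcm_features(np.ones((8, 8)), mask)


class TestLBPCodes:
    def test_constant_image_all_ones_code(self):
        codes = tf.lbp_codes(np.full((6, 6), 5.0))
        assert np.all(codes == 255)  # ties use >=, so every bit is set

    def test_single_bright_center(self):
        img = np.zeros((5, 5))
        img[2, 2] = 10.0
        codes = tf.lbp_codes(img)
        assert codes[1, 1] == 0  # bright center: no neighbour reaches it
        # every neighbour maps to one shared shift-minimal representative
        # (255: on the flat background the >= tie sets all bits, including
        # the one pointing at the bright pixel)
        neighbour_codes = [
            codes[i, j]
            for i in range(3)
            for j in range(3)
            if (i, j) != (1, 1)
        ]
        assert len(set(neighbour_codes)) == 1
        assert neighbour_codes[0] == 255

    def test_histogram_invariant_under_90_degree_rotation(self, rng):
        img = rng.uniform(0, 1, (12, 12))
        h1 = np.bincount(tf.lbp_codes(img).ravel(), minlength=256)
        h2 = np.bincount(tf.lbp_codes(np.rot90(img)).ravel(), minlength=256)
        np.testing.assert_array_equal(h1, h2)

    def test_intensity_shift_leaves_codes_unchanged(self, rng):
        img = rng.uniform(0, 1, (10, 10))
        np.testing.assert_array_equal(tf.lbp_codes(img), tf.lbp_codes(img + 123.0))

    def test_too_small_image_rejected(self):
        with pytest.raises(ShapeMismatchError):
            tf.lbp_codes(np.ones((2, 2)))

    def test_only_eight_point_ring_supported(self):
        with pytest.raises(ConfigurationError):
            tf.RICLBPConfig(n_points=16)


class TestRICLBP:
    def test_constant_image_single_bin(self):
        fv = tf.riclbp_features(np.full((10, 10), 2.0))
        d = dict(zip(fv.names, fv.values))
        assert d["riclbp_255_255"] == pytest.approx(1.0)
        assert fv.values.sum() == pytest.approx(1.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        img=hnp.arrays(float, (10, 10), elements=st.floats(0, 100, allow_nan=False))
    )
    def test_histogram_sums_to_one(self, img):
        assert tf.riclbp_features(img).values.sum() == pytest.approx(1.0)

    def test_rotation_invariance_on_random_binary_rasters(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            img = rng.integers(0, 2, (32, 32)).astype(float)
            base = tf.riclbp_features(img).values
            for k in (1, 2, 3):
                rotated = tf.riclbp_features(np.rot90(img, k)).values
                np.testing.assert_allclose(base, rotated, atol=1e-12)

    def test_masked_pairs_only(self, rng):
        img = rng.uniform(0, 1, (12, 12))
        mask = np.zeros((12, 12), bool)
        mask[:6] = True
        fv_masked = tf.riclbp_features(img, mask)
        fv_full = tf.riclbp_features(img)
        assert fv_masked.values.sum() == pytest.approx(1.0)
        assert not np.allclose(fv_masked.values, fv_full.values)


class TestExtractFeatures:
    def _pair(self, rng, n=16):
        b = ChannelImage(rng.uniform(0, 100, (n, n)), BLUE_BAND)
        g = ChannelImage(rng.uniform(0, 100, (n, n)), GREEN_BAND)
        return b, g

    def test_vector_length_and_schema(self, rng):
        b, g = self._pair(rng)
        fb, fg = tf.extract_features(b, g)
        n_pair_bins = len(tf.riclbp_names())
        assert len(fb.names) == 6 + 5 + n_pair_bins
        assert fb.names == fg.names
        assert fb.channel == BLUE_BAND and fg.channel == GREEN_BAND

    def test_swapping_channels_swaps_vectors(self, rng):
        b, g = self._pair(rng)
        fb, fg = tf.extract_features(b, g)
        b2 = ChannelImage(g.pixels, BLUE_BAND)
        g2 = ChannelImage(b.pixels, GREEN_BAND)
        fb2, fg2 = tf.extract_features(b2, g2)
        np.testing.assert_array_equal(fb.values, fg2.values)
        np.testing.assert_array_equal(fg.values, fb2.values)

    def test_feature_table_schema_stable(self, tiny_cohort_config):
        from rbcfluidity import synthetic_cohort as sc

        cohort = sc.simulate_cohort(tiny_cohort_config)
        table = tf.feature_table(cohort)
        assert len(table) == 6 * 2 * 2  # patients x z x channels
        assert {"patient", "group", "z", "channel"} <= set(table.columns)
        assert np.isfinite(
            table.drop(columns=["patient", "group", "z", "channel"]).to_numpy()
        ).all()
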