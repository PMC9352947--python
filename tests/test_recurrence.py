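"""Recurrence engine against brute-force oracles and its invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rp3d.recurrence import (EmbeddingParams, RecurrenceMatrix, embed,
                             normalize, resize_rp, rp_from_segment,
                             thresholded_rp, unthresholded_rp)


def brute_force_rp(points: np.ndarray) -> np.ndarray:
    """O(N^2) double-loop pairwise Euclidean distances."""
    pts = np.atleast_2d(points.T).T if points.ndim == 1 else points
    if pts.ndim == 1:
        pts = pts[:, None]
    n = pts.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = np.sqrt(np.sum((pts[i] - pts[j]) ** 2))
    return out


class TestEmbed:
    def test_identity_embedding(self):
        pts = embed(np.array([1.0, 2, 3, 4]), EmbeddingParams(m=1))
        assert pts.shape == (4, 1)
        np.testing.assert_array_equal(pts[:, 0], [1, 2, 3, 4])

    def test_m2_tau1_hand_enumeration(self):
        pts = embed(np.array([1.0, 2, 3, 4]), EmbeddingParams(m=2, tau=1))
        np.testing.assert_array_equal(pts, [[1, 2], [2, 3], [3, 4]])

    def test_point_count_formula(self):
        assert embed(np.zeros(1000), EmbeddingParams(m=1)).shape == (1000, 1)
        assert embed(np.zeros(100), EmbeddingParams(m=3, tau=7)).shape == (86, 3)

    def test_too_short_segment(self):
        with pytest.raises(ValueError, match="too short"):
            embed(np.zeros(5), EmbeddingParams(m=3, tau=3))

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            EmbeddingParams(m=0)
        with pytest.raises(ValueError):
            EmbeddingParams(m=2, tau=0)


class TestUnthresholded:
    def test_scalar_example(self):
        rp = unthresholded_rp(np.array([0.0, 1.0, 3.0]))
        np.testing.assert_array_equal(rp.values, [[0, 1, 3], [1, 0, 2], [3, 2, 0]])

    def test_constant_series_all_zero(self):
        rp = unthresholded_rp(np.full(10, 2.5))
        assert np.all(rp.values == 0)

    @pytest.mark.parametrize("m", [1, 2, 3])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, m, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(60)
        pts = embed(x, EmbeddingParams(m=m, tau=2))
        rp = unthresholded_rp(pts)
        np.testing.assert_allclose(rp.values, brute_force_rp(pts), atol=1e-12)

    def test_symmetry_zero_diagonal_triangle(self):
        rng = np.random.default_rng(3)
        pts = embed(rng.standard_normal(40), EmbeddingParams(m=2, tau=1))
        v = unthresholded_rp(pts).values
        np.testing.assert_allclose(v, v.T, atol=0)
        assert np.all(np.diag(v) == 0)
        n = v.shape[0]
        lhs = v[:, None, :]                    # R[i,k]
        rhs = v[:, :, None] + v[None, :, :]    # R[i,j] + R[j,k]
        assert np.all(lhs <= rhs + 1e-9)


class TestThresholded:
    def test_hand_example(self):
        rp = thresholded_rp(np.array([0.0, 1.0, 3.0]), epsilon=1.5)
        np.testing.assert_array_equal(rp.values, [[1, 1, 0], [1, 1, 0], [0, 0, 1]])

    def test_indicator_equivalence(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(50)
        eps = 0.8
        dist = unthresholded_rp(x).values
        np.testing.assert_array_equal(thresholded_rp(x, eps).values,
                                      (dist <= eps).astype(float))

    def test_boundary_counts_as_recurrent(self):
        # distance between x0 and x1 is exactly 1.0
        rp = thresholded_rp(np.array([0.0, 1.0, 5.0]), epsilon=1.0)
        assert rp.values[0, 1] == 1.0

    def test_saturation_and_diagonal(self):
        x = np.array([0.0, 1.0, 3.0])
        assert np.all(thresholded_rp(x, epsilon=10.0).values == 1)
        assert np.all(np.diag(thresholded_rp(x, epsilon=0.5).values) == 1)

    def test_nonpositive_epsilon_rejected(self):
        with pytest.raises(ValueError):
            thresholded_rp(np.array([0.0, 1.0]), epsilon=0.0)


class TestNormalize:
    def test_minmax_example(self):
        rp = RecurrenceMatrix(np.array([[0.0, 2], [2, 4]]))
        np.testing.assert_allclose(normalize(rp, "minmax").values,
                                   [[0, 0.5], [0.5, 1]])

    def test_degenerate_constant_matrix(self):
        rp = RecurrenceMatrix(np.full((4, 4), 3.0))
        assert np.all(normalize(rp, "minmax").values == 0)
        assert np.all(normalize(rp, "zscore").values == 0)

    def test_zscore_moments(self):
        rng = np.random.default_rng(5)
        rp = unthresholded_rp(rng.standard_normal(30))
        z = normalize(rp, "zscore").values
        assert abs(z.mean()) < 1e-10
        assert abs(z.std() - 1) < 1e-10

    @given(scale=st.floats(0.1, 100), offset=st.floats(-5, 5))
    @settings(deadline=None, max_examples=25)
    def test_minmax_invariant_to_affine_rescaling(self, scale, offset):
        x = np.random.default_rng(6).standard_normal(25)
        a = normalize(unthresholded_rp(x), "minmax").values
        b = normalize(unthresholded_rp(scale * x + offset), "minmax").values
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            normalize(RecurrenceMatrix(np.zeros((2, 2))), "quantile")


class TestResize:
    def test_ones_stay_ones(self):
        rp = RecurrenceMatrix(np.ones((4, 4)))
        np.testing.assert_array_equal(resize_rp(rp, 2).values, np.ones((2, 2)))

    def test_block_mean_example(self):
        v = np.array([[0.0, 0, 2, 2], [0, 0, 2, 2], [2, 2, 0, 0], [2, 2, 0, 0]])
        np.testing.assert_array_equal(resize_rp(RecurrenceMatrix(v), 2).values,
                                      [[0, 2], [2, 0]])

    def test_symmetry_preserved(self):
        rng = np.random.default_rng(7)
        rp = unthresholded_rp(rng.standard_normal(100))
        out = resize_rp(rp, 17).values     # non-divisible side on purpose
        assert np.max(np.abs(out - out.T)) < 1e-12

    def test_mean_preserved_when_divisible(self):
        rng = np.random.default_rng(8)
        rp = unthresholded_rp(rng.standard_normal(64))
        out = resize_rp(rp, 16)
        assert abs(out.values.mean() - rp.values.mean()) < 1e-12

    def test_upsizing_rejected(self):
        with pytest.raises(ValueError, match="downsampling"):
            resize_rp(RecurrenceMatrix(np.zeros((4, 4))), 8)
        with pytest.raises(ValueError):
            resize_rp(RecurrenceMatrix(np.zeros((4, 4))), 1)


def test_rp_exports(tmp_path):
    import h5py

    rng = np.random.default_rng(10)
    rp = normalize(unthresholded_rp(rng.standard_normal(40)), "zscore")
    png = __import__("rp3d.recurrence", fromlist=["save_rp_png"]).save_rp_png(
        rp, tmp_path / "rp.png")
    from PIL import Image

    img = Image.open(png)
    assert img.size == (40, 40) and img.mode == "L"
    h5 = __import__("rp3d.recurrence", fromlist=["save_rp_hdf5"]).save_rp_hdf5(
        rp, tmp_path / "rp.h5")
    with h5py.File(h5) as f:
        assert f["rp"].shape == (40, 40)
        assert f["rp"].dtype == np.float32
        assert f["rp"].attrs["normalization"] == "zscore"


def test_rp_from_segment_pipeline():
    rng = np.random.default_rng(9)
    seg = rng.standard_normal(500)
    rp = rp_from_segment(seg, EmbeddingParams(), "zscore", side=64)
    assert rp.values.shape == (64, 64)
    assert rp.normalization == "zscore"
    dec = rp_from_segment(seg, EmbeddingParams(), "none", side=None, decimate=4)
    assert dec.values.shape == (125, 125)
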