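"""Global feature extractors against brute-force counting oracles."""

import numpy as np
import pytest

from modclass.features_global import (
    color_histogram,
    edge_histogram,
    gray_histogram,
    normalize_histogram,
    standardize,
    to_grayscale,
    variance_histogram,
)


class TestNormalizeHistogram:
    @pytest.mark.parametrize(
        "counts,expected",
        [([2, 2], [0.5, 0.5]), ([1, 3], [0.25, 0.75]), ([0, 0, 0], [0, 0, 0])],
    )
    def test_examples(self, counts, expected):
        np.testing.assert_allclose(normalize_histogram(counts), expected)

    def test_matches_division_oracle(self, rng):
        counts = rng.uniform(0, 10, 50)
        out = normalize_histogram(counts)
        assert abs(out.sum() - 1.0) < 1e-12
        total = sum(float(c) for c in counts)
        for i, c in enumerate(counts):
            assert out[i] == pytest.approx(c / total, abs=1e-15)

    @pytest.mark.parametrize("bad", [[-1, 2], [np.nan, 1], [np.inf, 0]])
    def test_invalid_entries_rejected(self, bad):
        with pytest.raises(ValueError):
            normalize_histogram(bad)


class TestGrayHistogram:
    def test_constant_image_is_one_hot(self):
        h = gray_histogram(np.full((8, 8), 7))
        assert h[7] == 1.0 and h.sum() == 1.0

    def test_two_value_image(self):
        img = np.array([[0, 0], [255, 255]])
        h = gray_histogram(img)
        assert h[0] == 0.5 and h[255] == 0.5

    @pytest.mark.parametrize("n_bins", [256, 16, 7])
    def test_matches_counting_oracle(self, rng, n_bins):
        img = rng.integers(0, 256, (16, 16))
        h = gray_histogram(img, n_bins)
        oracle = np.zeros(n_bins)
        for v in img.ravel():
            oracle[min(v * n_bins // 256, n_bins - 1)] += 1
        np.testing.assert_allclose(h, oracle / img.size)

    def test_rgb_input_converted_by_luminance(self):
        img = np.zeros((4, 4, 3), dtype=int)
        img[..., 1] = 200  # pure green -> round(0.587 * 200) = 117
        assert gray_histogram(img)[117] == 1.0

    def test_invalid_bins(self, gray_image):
        with pytest.raises(ValueError):
            gray_histogram(gray_image, n_bins=0)


class TestColorHistogram:
    def test_single_joint_bin(self, rgb_image):
        np.testing.assert_allclose(color_histogram(rgb_image, (1, 1, 1)), [1.0])

    def test_solid_red_one_hot(self):
        img = np.zeros((4, 4, 3), dtype=int)
        img[..., 0] = 255
        h = color_histogram(img, (2, 2, 2))
        expected = np.zeros(8)
        expected[(1 * 2 + 0) * 2 + 0] = 1.0  # joint bin (1, 0, 0), red-major
        np.testing.assert_allclose(h, expected)

    def test_matches_quantize_and_count_oracle(self, rng):
        img = rng.integers(0, 256, (8, 8, 3))
        k = m = l = 4
        h = color_histogram(img, (k, m, l))
        oracle = np.zeros(k * m * l)
        for row in img.reshape(-1, 3):
            r, g, b = (int(v) for v in row)
            oracle[(r * k // 256 * m + g * m // 256) * l + b * l // 256] += 1
        np.testing.assert_allclose(h, oracle / 64)

    def test_grayscale_rejected(self, gray_image):
        with pytest.raises(ValueError):
            color_histogram(gray_image)

    def test_invalid_bins(self, rgb_image):
        with pytest.raises(ValueError):
            color_histogram(rgb_image, (0, 4, 4))


def _edge_oracle(img, grid, n_bins):
    """Direct per-pixel gradient accumulation with explicit loops."""
    gray = to_grayscale(img).astype(float)
    h, w = gray.shape
    p = np.pad(gray, 1, mode="edge")
    out = np.zeros(grid[0] * grid[1] * n_bins)
    redges = [h * i // grid[0] for i in range(grid[0] + 1)]
    cedges = [w * j // grid[1] for j in range(grid[1] + 1)]
    for bi in range(grid[0]):
        for bj in range(grid[1]):
            hist = np.zeros(n_bins)
            for r in range(redges[bi], redges[bi + 1]):
                for c in range(cedges[bj], cedges[bj + 1]):
                    gx = (p[r + 1, c + 2] - p[r + 1, c]) / 2
                    gy = (p[r + 2, c + 1] - p[r, c + 1]) / 2
                    mag = np.hypot(gx, gy)
                    theta = np.degrees(np.arctan2(gy, gx)) % 360.0
                    hist[min(int(theta * n_bins / 360), n_bins - 1)] += mag
            if hist.sum() > 0:
                hist /= hist.sum()
            out[(bi * grid[1] + bj) * n_bins : (bi * grid[1] + bj + 1) * n_bins] = hist
    return out


class TestEdgeHistogram:
    def test_default_dimension_is_320(self, gray_image):
        assert edge_histogram(gray_image).shape == (320,)

    def test_constant_image_all_zero(self):
        assert not edge_histogram(np.full((16, 16), 42)).any()

    def test_vertical_step_edge_mass_and_oracle(self, rng):
        img = np.zeros((16, 16), dtype=int)
        img[:, 8:] = 255
        h = edge_histogram(img, grid=(1, 1), n_bins=20)
        oracle = _edge_oracle(img, (1, 1), 20)
        np.testing.assert_allclose(h, oracle, atol=1e-12)
        # horizontal gradients: orientations 0 and 180 degrees -> bins 0 and 10
        assert h[0] + h[10] >= 0.9

    def test_matches_gradient_oracle_random(self, rng):
        img = rng.integers(0, 256, (17, 23))
        h = edge_histogram(img, grid=(4, 4), n_bins=20)
        np.testing.assert_allclose(h, _edge_oracle(img, (4, 4), 20), atol=1e-12)

    def test_half_turn_rotation_shifts_orientation_bins(self, rng):
        """Rotating the image 180 deg maps orientation theta -> theta + 180."""
        img = rng.integers(0, 256, (20, 20))
        h = edge_histogram(img, grid=(1, 1), n_bins=20)
        h_rot = edge_histogram(img[::-1, ::-1], grid=(1, 1), n_bins=20)
        np.testing.assert_allclose(h_rot, np.roll(h, 10), atol=1e-9)

    def test_image_smaller_than_grid_rejected(self):
        with pytest.raises(ValueError):
            edge_histogram(np.zeros((2, 2), dtype=int), grid=(4, 4))


class TestVarianceHistogram:
    def test_constant_image_one_hot_at_zero(self):
        h = variance_histogram(np.full((8, 8), 100))
        assert h[0] == 1.0

    @pytest.mark.parametrize("n_bins", [32, 8])
    def test_length_contract(self, gray_image, n_bins):
        assert variance_histogram(gray_image, n_bins=n_bins).shape == (n_bins,)

    def test_matches_patch_variance_loop_oracle(self, rng):
        img = rng.integers(0, 256, (32, 32))
        r, n_bins = 2, 32
        h = variance_histogram(img, patch_radius=r, n_bins=n_bins)
        width = 255.0**2 / 4.0 / n_bins
        oracle = np.zeros(n_bins)
        count = 0
        gray = img.astype(float)
        for i in range(r, 32 - r):
            for j in range(r, 32 - r):
                patch = gray[i - r : i + r + 1, j - r : j + r + 1]
                oracle[min(int(patch.var() / width), n_bins - 1)] += 1
                count += 1
        np.testing.assert_allclose(h, oracle / count)

    def test_image_too_small_rejected(self):
        with pytest.raises(ValueError):
            variance_histogram(np.zeros((3, 3), dtype=int), patch_radius=2)


class TestSharedProperties:
    @pytest.mark.parametrize("extract", [gray_histogram, color_histogram])
    def test_pixel_permutation_invariance(self, rng, extract):
        img = rng.integers(0, 256, (12, 12, 3))
        flat = img.reshape(-1, 3)
        shuffled = flat[rng.permutation(len(flat))].reshape(12, 12, 3)
        np.testing.assert_array_equal(extract(img), extract(shuffled))

    @pytest.mark.parametrize("extract", [edge_histogram, variance_histogram])
    def test_spatial_features_not_permutation_invariant(self, extract):
        rng = np.random.default_rng(7)
        img = np.tile(np.arange(0, 256, 16), (16, 1)).T  # strong vertical structure
        shuffled = img.ravel()[rng.permutation(img.size)].reshape(img.shape)
        assert not np.array_equal(extract(img), extract(shuffled))

    def test_extractors_deterministic(self, rgb_image):
        for fn in (gray_histogram, color_histogram, edge_histogram, variance_histogram):
            a, b = fn(rgb_image), fn(rgb_image)
            assert a.tobytes() == b.tobytes()

    def test_histograms_sum_to_one(self, rng):
        img = rng.integers(0, 256, (24, 24, 3))
        for h in (
            gray_histogram(img),
            color_histogram(img),
            variance_histogram(img),
        ):
            assert abs(h.sum() - 1.0) < 1e-9
        # edge histogram: each of the 16 blocks sums to 1 independently
        e = edge_histogram(img).reshape(16, 20)
        np.testing.assert_allclose(e.sum(axis=1), 1.0, atol=1e-9)

    def test_standardize_shape_and_identity(self, rgb_image):
        out = standardize(rgb_image, 64)
        assert out.shape == (64, 64, 3)
        same = standardize(rgb_image, 32)
        np.testing.assert_array_equal(same, np.asarray(rgb_image))

    @pytest.mark.parametrize("bad", [np.full((4, 4), 300), np.full((4, 4), -1),
                                     np.zeros((4, 4, 2), dtype=int)])
    def test_invalid_images_rejected(self, bad):
        with pytest.raises(ValueError):
            gray_histogram(bad) if bad.ndim == 2 else to_grayscale(bad)
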