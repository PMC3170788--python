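"""Distance metrics, gamma normalization, RBF kernels and equal-contribution fusion."""

import numpy as np
import pytest

from modclass.kernels import (
    compute_gamma,
    cross_distances,
    feature_distance,
    jkec_combine,
    pairwise_distances,
    rbf_kernel,
)


def _loop_distance(x, y, metric):
    if metric == "L1":
        return sum(abs(a - b) for a, b in zip(x, y))
    if metric == "L2":
        return sum((a - b) ** 2 for a, b in zip(x, y)) ** 0.5
    return sum((a - b) ** 2 / (a + b) for a, b in zip(x, y) if a + b > 0)


class TestFeatureDistance:
    @pytest.mark.parametrize(
        "x,y,metric,expected",
        [
            ([0.3, 0.7], [0.3, 0.7], "chi2", 0.0),
            ([1, 0], [0, 1], "chi2", 2.0),
            ([1, 2], [3, 1], "L1", 3.0),
            ([0, 3], [4, 0], "L2", 5.0),
        ],
    )
    def test_hand_computed_values(self, x, y, metric, expected):
        assert feature_distance(x, y, metric) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize("metric", ["L1", "L2", "chi2"])
    def test_matches_loop_oracle(self, rng, metric):
        for _ in range(50):
            x = rng.uniform(0, 1, 20)
            y = rng.uniform(0, 1, 20)
            assert feature_distance(x, y, metric) == pytest.approx(
                _loop_distance(x, y, metric), abs=1e-12
            )

    def test_metric_axioms(self, rng):
        x, y = rng.uniform(0, 1, 10), rng.uniform(0, 1, 10)
        for metric in ("L1", "L2", "chi2"):
            assert feature_distance(x, y, metric) >= 0
            assert feature_distance(x, y, metric) == pytest.approx(
                feature_distance(y, x, metric), abs=1e-12
            )
            assert feature_distance(x, x, metric) == 0.0
        # chi2(x, y) = 0 iff x = y on nonnegative vectors
        assert feature_distance(x, np.where(x > 0, x, 0) + 1e-3, "chi2") > 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            feature_distance([1, 2], [1, 2, 3], "L1")
        with pytest.raises(ValueError):
            feature_distance([-1, 2], [1, 2], "chi2")
        with pytest.raises(ValueError):
            feature_distance([1, 2], [1, 2], "cosine")


class TestPairwiseDistances:
    def test_degenerate_cases(self):
        np.testing.assert_array_equal(pairwise_distances([[1.0, 2.0]]), [[0.0]])
        np.testing.assert_array_equal(
            pairwise_distances([[1.0, 2.0], [1.0, 2.0]]), np.zeros((2, 2))
        )

    @pytest.mark.parametrize("metric", ["L1", "L2", "chi2"])
    def test_matches_double_loop_oracle(self, rng, metric):
        x = rng.uniform(0, 1, (10, 6))
        d = pairwise_distances(x, metric)
        for i in range(10):
            for j in range(10):
                assert d[i, j] == pytest.approx(
                    _loop_distance(x[i], x[j], metric), abs=1e-12
                )
        assert np.all(np.diag(d) == 0)
        np.testing.assert_array_equal(d, d.T)

    def test_cross_distances_rectangular(self, rng):
        a, b = rng.uniform(0, 1, (3, 5)), rng.uniform(0, 1, (4, 5))
        d = cross_distances(a, b, "chi2")
        assert d.shape == (3, 4)
        assert d[1, 2] == pytest.approx(_loop_distance(a[1], b[2], "chi2"), abs=1e-12)


class TestGamma:
    def test_two_sample_hand_case(self):
        d = np.array([[0.0, 3.0], [3.0, 0.0]])
        assert compute_gamma(d) == pytest.approx(1.5)  # (0+3+3+0)/4

    def test_all_zero_falls_back_with_warning(self):
        with pytest.warns(UserWarning):
            assert compute_gamma(np.zeros((4, 4))) == 1.0

    def test_matches_brute_force_double_sum(self, rng):
        d = rng.uniform(0, 5, (20, 20))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        oracle = sum(d[i, j] for i in range(20) for j in range(20)) / 400
        assert compute_gamma(d) == pytest.approx(oracle, rel=1e-12)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            compute_gamma(np.zeros((3, 4)))


class TestRbfKernel:
    def test_analytic_values(self):
        assert rbf_kernel(np.zeros((2, 2)), 1.0)[0, 0] == 1.0
        g = 0.7
        assert rbf_kernel(np.full((1, 1), g), g)[0, 0] == pytest.approx(np.exp(-1))

    def test_matches_exp_loop_oracle(self, rng):
        d = rng.uniform(0, 3, (6, 6))
        k = rbf_kernel(d, 0.9)
        for i in range(6):
            for j in range(6):
                assert k[i, j] == pytest.approx(np.exp(-d[i, j] / 0.9), abs=1e-12)

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(ValueError):
            rbf_kernel(np.zeros((2, 2)), 0.0)


class TestJkecFusion:
    def test_single_kernel_identity(self, rng):
        k = rng.uniform(0.1, 1, (4, 4))
        np.testing.assert_array_equal(jkec_combine([k]), k)

    def test_constant_kernels_mean(self):
        out = jkec_combine([np.full((3, 3), 0.2), np.full((3, 3), 0.6)])
        np.testing.assert_allclose(out, 0.4)

    def test_matches_elementwise_loop_mean(self, rng):
        ks = [rng.uniform(0.01, 1, (5, 5)) for _ in range(5)]
        fused = jkec_combine(ks)
        for i in range(5):
            for j in range(5):
                assert fused[i, j] == pytest.approx(
                    sum(k[i, j] for k in ks) / 5, abs=1e-12
                )

    def test_weighted_fusion_hook(self, rng):
        ks = [np.full((2, 2), 0.2), np.full((2, 2), 0.6)]
        np.testing.assert_allclose(jkec_combine(ks, weights=[0.25, 0.75]), 0.5)
        with pytest.raises(ValueError):
            jkec_combine(ks, weights=[0.5, 0.6])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            jkec_combine([np.zeros((2, 2)), np.zeros((3, 3))])


class TestEqualContribution:
    @pytest.mark.parametrize("metric", ["L1", "L2", "chi2"])
    @pytest.mark.parametrize("shape", [(8, 5), (25, 40)])
    def test_normalized_distances_average_to_one(self, rng, metric, shape):
        """The testable content of "each feature contributes equally"."""
        x = rng.uniform(0, 1, shape)
        d = pairwise_distances(x, metric)
        gamma = compute_gamma(d)
        assert np.mean(d / gamma) == pytest.approx(1.0, abs=1e-9)

    def test_kernel_range_and_fused_inheritance(self, rng):
        feats = [rng.uniform(0, 1, (12, d)) for d in (4, 9, 30)]
        kernels = []
        for x in feats:
            d = pairwise_distances(x, "chi2")
            k = rbf_kernel(d, compute_gamma(d))
            assert np.all(k > 0) and np.all(k <= 1)
            np.testing.assert_array_equal(np.diag(k), 1.0)
            np.testing.assert_array_equal(k, k.T)
            kernels.append(k)
        fused = jkec_combine(kernels)
        assert np.all(fused > 0) and np.all(fused <= 1)
        np.testing.assert_array_equal(np.diag(fused), 1.0)
        np.testing.assert_array_equal(fused, fused.T)

    @pytest.mark.parametrize("metric", ["L1", "L2"])
    def test_scale_robustness(self, rng, metric):
        """Rescaling a feature rescales gamma identically, leaving the kernel fixed."""
        x = rng.uniform(0, 1, (10, 7))
        d1 = pairwise_distances(x, metric)
        k1 = rbf_kernel(d1, compute_gamma(d1))
        d2 = pairwise_distances(x * 37.5, metric)
        k2 = rbf_kernel(d2, compute_gamma(d2))
        np.testing.assert_allclose(k1, k2, atol=1e-9)
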