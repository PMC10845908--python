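import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import neupredict as nm
from neupredict import LocalFitConfig, local_poly_fit, predict_nonsampled, smoother_weights
from neupredict.smoothing import smoother_weight_matrix

NW_AT_ZERO = 0.37754066879814546  # K(1)/(K(0)+K(1)) by hand


class TestLocalPolyFit:
    @pytest.mark.parametrize("h", [0.1, 0.5, 5.0])
    @pytest.mark.parametrize("x0", [-0.3, 0.0, 0.4, 1.7])
    def test_local_linear_reproduces_affine_data(self, h, x0):
        xs = np.array([0.0, 1.0])
        cfg = LocalFitConfig(degree=1, bandwidth=h)
        assert local_poly_fit(xs, xs, x0, cfg) == pytest.approx(x0, abs=1e-8)

    def test_nadaraya_watson_by_hand(self):
        cfg = LocalFitConfig(degree=0, bandwidth=1.0)
        got = local_poly_fit([0.0, 1.0], [0.0, 1.0], 0.0, cfg)
        assert got == pytest.approx(NW_AT_ZERO, abs=1e-9)

    @pytest.mark.parametrize("p", [0, 1, 2])
    def test_constants_reproduced(self, p):
        xs = np.linspace(0, 1, 9)
        cfg = LocalFitConfig(degree=p, bandwidth=0.3)
        assert local_poly_fit(xs, np.full(9, 4.2), 0.37, cfg) == pytest.approx(4.2)

    def test_huge_bandwidth_limit_is_global_ols(self):
        rng = np.random.default_rng(8)
        xs = rng.uniform(0, 1, 30)
        ys = 1.0 + 2.0 * xs + rng.normal(0, 0.3, 30)
        slope, intercept = np.polyfit(xs, ys, 1)  # independent oracle
        cfg = LocalFitConfig(degree=1, bandwidth=1e6)
        for x0 in (0.1, 0.5, 0.9):
            assert local_poly_fit(xs, ys, x0, cfg) == pytest.approx(
                intercept + slope * x0, abs=1e-6
            )

    def test_polynomial_reproduction_degree_two(self):
        xs = np.linspace(0, 1, 12)
        ys = 1.0 - 0.5 * xs + 2.0 * xs**2
        cfg = LocalFitConfig(degree=2, bandwidth=0.5)
        assert local_poly_fit(xs, ys, 0.3, cfg) == pytest.approx(
            1.0 - 0.5 * 0.3 + 2.0 * 0.09, abs=1e-8
        )

    @given(
        st.floats(-3, 3), st.floats(-3, 3), st.floats(-3, 3), st.floats(-3, 3)
    )
    def test_linearity_in_y(self, a, b, c, d):
        xs = np.array([0.0, 0.4, 0.7, 1.0])
        y1 = np.array([1.0, -1.0, 2.0, 0.5])
        y2 = np.array([0.3, 0.9, -0.2, 1.1])
        cfg = LocalFitConfig(degree=1, bandwidth=0.3)
        lhs = local_poly_fit(xs, a * y1 + b * y2, c * 0 + 0.5, cfg)
        rhs = a * local_poly_fit(xs, y1, 0.5, cfg) + b * local_poly_fit(xs, y2, 0.5, cfg)
        assert lhs == pytest.approx(rhs, abs=1e-10)


class TestSmootherWeights:
    def test_weights_reproduce_fit(self):
        rng = np.random.default_rng(9)
        xs = rng.uniform(0, 1, 20)
        ys = rng.normal(size=20)
        for p in (0, 1, 2):
            cfg = LocalFitConfig(degree=p, bandwidth=0.25)
            w = smoother_weights(xs, 0.6, cfg)
            assert w @ ys == pytest.approx(local_poly_fit(xs, ys, 0.6, cfg), abs=1e-12)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(10)
        xs = rng.uniform(0, 1, 15)
        for p in (0, 1):
            for x0 in (0.0, 0.5, 1.2):
                w = smoother_weights(xs, x0, LocalFitConfig(degree=p, bandwidth=0.2))
                assert w.sum() == pytest.approx(1.0, abs=1e-10)

    def test_normalized_kernel_weights_degree_zero(self):
        w = smoother_weights([0.0, 1.0], 0.0, LocalFitConfig(degree=0, bandwidth=1.0))
        np.testing.assert_allclose(w, [1 - NW_AT_ZERO, NW_AT_ZERO], atol=1e-9)

    def test_underflow_falls_back_to_nearest_neighbor(self):
        # x0 astronomically far from every sample point: all weights underflow
        w = smoother_weights([0.0, 1.0], 1e6, LocalFitConfig(degree=1, bandwidth=0.01))
        np.testing.assert_array_equal(w, [0.0, 1.0])

    def test_batch_matrix_agrees_with_single_point_path(self):
        rng = np.random.default_rng(11)
        xs = rng.uniform(0, 1, 25)
        x0s = rng.uniform(0, 1, 12)
        cfg = LocalFitConfig(degree=1, bandwidth=0.15)
        W, n_degen = smoother_weight_matrix(xs, x0s, cfg)
        assert n_degen == 0
        # batch path carries a relative ridge of 1e-10; agreement to ~1e-9
        for j, x0 in enumerate(x0s):
            np.testing.assert_allclose(W[j], smoother_weights(xs, x0, cfg), atol=1e-9)


class TestPredictNonsampled:
    def test_affine_population_predicted_exactly(self, affine_pop, small_sample):
        s = small_sample(40, 10, seed=1)
        preds = predict_nonsampled(
            affine_pop, s, nm.BandwidthSpec("fixed", value=0.3), LocalFitConfig()
        )
        mask = np.ones(40, dtype=bool)
        mask[s.indices] = False
        np.testing.assert_allclose(preds.lower, affine_pop.y.lower[mask], atol=1e-8)
        np.testing.assert_allclose(preds.upper, affine_pop.y.upper[mask], atol=1e-8)

    def test_single_holdout_reduces_to_pointwise_fit(self, sine_pop):
        N = sine_pop.N
        s = nm.SampleIndex(np.arange(1, N), N - 1)
        cfg = LocalFitConfig(degree=1, bandwidth=0.2)
        preds = predict_nonsampled(sine_pop, s, nm.BandwidthSpec("fixed", value=0.2), cfg)
        assert len(preds) == 1
        expected = local_poly_fit(
            sine_pop.x.lower[1:], sine_pop.y.lower[1:], sine_pop.x.lower[0], cfg
        )
        # batch path carries a relative ridge of 1e-10
        assert preds.lower[0] == pytest.approx(expected, abs=1e-9)

    def test_four_unit_toy_population_hand_weighted_least_squares(self):
        # hand-worked WLS at each held-out point, independent matrix algebra
        x = np.array([0.0, 0.3, 0.6, 1.0])
        y = np.array([1.0, 0.2, -0.4, 2.0])
        pop = nm.NeutroPopulation(
            nm.NeutroArray(x, x), nm.NeutroArray(y, y), 4, name="toy"
        )
        s = nm.SampleIndex(np.array([0, 3]), 2)
        h = 0.5
        cfg = LocalFitConfig(degree=1, bandwidth=h, ridge=0.0)
        preds = predict_nonsampled(pop, s, nm.BandwidthSpec("fixed", value=h), cfg)
        for k, x0 in enumerate([0.3, 0.6]):
            d = x[[0, 3]] - x0
            K = np.exp(-0.5 * (d / h) ** 2) / (h * np.sqrt(2 * np.pi))
            X = np.column_stack([np.ones(2), d])
            beta = np.linalg.solve(X.T @ np.diag(K) @ X, X.T @ np.diag(K) @ y[[0, 3]])
            assert preds.lower[k] == pytest.approx(beta[0], abs=1e-10)

    def test_output_ordered_by_population_index(self, sine_pop):
        s = nm.SampleIndex(np.array([5, 1, 900]), 3)
        preds = predict_nonsampled(
            sine_pop, s, nm.BandwidthSpec("fixed", value=0.2), LocalFitConfig()
        )
        assert len(preds) == sine_pop.N - 3
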