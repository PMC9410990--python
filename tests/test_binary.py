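import numpy as np
import pytest

from lcnc import (fit_lssvm, fit_plsda, predict_lssvm, predict_plsda,
                  rbf_kernel)


class TestPLSDA:
    def test_separable_blobs_one_lv(self, blobs):
        X, y = blobs
        model = fit_plsda(X, y, n_lv=1)
        _, signs = predict_plsda(model, X)
        np.testing.assert_array_equal(signs, y)

    def test_full_rank_equals_least_squares(self, rng):
        X = rng.standard_normal((30, 4))
        y = np.sign(rng.standard_normal(30))
        y[:2] = [1.0, -1.0]
        model = fit_plsda(X, y, n_lv=4)
        fitted, _ = predict_plsda(model, X)
        A = np.column_stack([np.ones(30), X])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        np.testing.assert_allclose(fitted, A @ beta, atol=1e-6)

    def test_first_weight_proportional_to_xty(self, rng):
        X = rng.standard_normal((25, 3))
        y = np.sign(rng.standard_normal(25))
        y[:2] = [1.0, -1.0]
        model = fit_plsda(X, y, n_lv=1)
        Xs = (X - model.x_center) / model.x_scale
        w_expected = Xs.T @ (y - y.mean())
        w_expected /= np.linalg.norm(w_expected)
        np.testing.assert_allclose(np.abs(model.weights[:, 0]),
                                   np.abs(w_expected), rtol=1e-10)

    def test_balanced_threshold_midway_between_class_means(self, rng):
        # a severely imbalanced one-vs-rest style fit
        X = np.vstack([rng.normal(0, 1, (5, 3)), rng.normal(2, 1, (40, 3))])
        y = np.concatenate([np.ones(5), -np.ones(40)])
        model = fit_plsda(X, y, n_lv=2, class_weighting=True)
        fitted, _ = predict_plsda(model, X)
        mid = 0.5 * (fitted[y > 0].mean() + fitted[y < 0].mean())
        assert model.decision_threshold == pytest.approx(mid)
        # without weighting the threshold stays at the response origin
        assert fit_plsda(X, y, n_lv=2).decision_threshold == 0.0

    def test_score_orthogonality(self, blobs):
        X, y = blobs
        model = fit_plsda(X, y, n_lv=2)
        Xs = (X - model.x_center) / model.x_scale
        T = np.empty((len(X), 2))
        Xd = Xs.copy()
        for a in range(2):
            T[:, a] = Xd @ model.weights[:, a]
            Xd = Xd - np.outer(T[:, a], model.loadings[:, a])
        assert abs(T[:, 0] @ T[:, 1]) < 1e-8

    def test_duplicate_row_duplicate_response(self, blobs):
        X, y = blobs
        model = fit_plsda(X, y, n_lv=1)
        r, _ = predict_plsda(model, np.vstack([X[3], X[3]]))
        assert r[0] == r[1]

    def test_feature_rescaling_preserves_signs(self, blobs):
        X, y = blobs
        m1 = fit_plsda(X, y, n_lv=2)
        m2 = fit_plsda(X * np.array([10.0, 0.01]), y, n_lv=2)
        _, s1 = predict_plsda(m1, X)
        _, s2 = predict_plsda(m2, X * np.array([10.0, 0.01]))
        np.testing.assert_array_equal(s1, s2)

    def test_errors(self, blobs):
        X, y = blobs
        with pytest.raises(ValueError, match="n_lv"):
            fit_plsda(X, y, n_lv=3)  # p = 2
        with pytest.raises(ValueError, match="both"):
            fit_plsda(X, np.ones(len(y)), n_lv=1)
        m = fit_plsda(X, y, n_lv=1)
        with pytest.raises(ValueError, match="columns"):
            predict_plsda(m, np.zeros((2, 5)))

    def test_rank_deficiency_detected(self, rng):
        col = rng.standard_normal(20)
        X = np.column_stack([col, col, col])  # rank 1 after centering
        y = np.sign(col)
        with pytest.raises(ValueError, match="rank"):
            fit_plsda(X, y, n_lv=3)

    def test_deterministic(self, blobs):
        X, y = blobs
        a = fit_plsda(X, y, n_lv=2)
        b = fit_plsda(X, y, n_lv=2)
        np.testing.assert_array_equal(a.regression_vector,
                                      b.regression_vector)

    @pytest.mark.parametrize("n_lv", [1, 2, 4])
    def test_matches_sklearn_pls_regression(self, rng, n_lv):
        # independent oracle: scikit-learn's NIPALS PLS with scaling on
        from sklearn.cross_decomposition import PLSRegression
        X = rng.standard_normal((30, 6))
        y = np.sign(rng.standard_normal(30))
        y[:2] = [1.0, -1.0]
        ours, _ = predict_plsda(fit_plsda(X, y, n_lv), X)
        theirs = PLSRegression(n_components=n_lv, scale=True).fit(X, y)
        np.testing.assert_allclose(ours, theirs.predict(X).ravel(),
                                   atol=1e-10)


class TestRBF:
    def test_unit_diagonal(self, rng):
        X = rng.standard_normal((6, 3))
        np.testing.assert_allclose(np.diag(rbf_kernel(X, X, 2.0)), 1.0,
                                   atol=1e-12)

    def test_distance_sigma_gives_e_minus_one(self):
        K = rbf_kernel([[0.0, 0.0]], [[3.0, 4.0]], sigma=5.0)
        assert K[0, 0] == pytest.approx(np.exp(-1))

    def test_wide_kernel_limit(self, rng):
        X = rng.standard_normal((5, 2))
        K = rbf_kernel(X, X, sigma=1e8)
        np.testing.assert_allclose(K, 1.0, atol=1e-12)

    def test_sigma_validation(self):
        with pytest.raises(ValueError):
            rbf_kernel([[0.0]], [[1.0]], sigma=0.0)


XOR_X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
XOR_Y = np.array([1.0, 1.0, -1.0, -1.0])


class TestLSSVM:
    def test_xor_is_separated(self):
        model = fit_lssvm(XOR_X, XOR_Y, sigma=0.7, gamma=1e4)
        _, signs = predict_lssvm(model, XOR_X)
        np.testing.assert_array_equal(signs, XOR_Y)

    def test_alphas_sum_to_zero(self, blobs):
        X, y = blobs
        model = fit_lssvm(X, y, sigma=2.0, gamma=10.0)
        assert abs(model.alphas.sum()) < 1e-8

    def test_kkt_residual_tiny(self, blobs):
        X, y = blobs
        model = fit_lssvm(X, y, sigma=2.0, gamma=10.0)
        assert model.kkt_residual <= 1e-8

    def test_matches_generic_solver(self, blobs):
        X, y = blobs
        sigma, gamma = 1.5, 7.0
        model = fit_lssvm(X, y, sigma, gamma)
        n = len(y)
        K = rbf_kernel(X, X, sigma)
        A = np.zeros((n + 1, n + 1))
        A[0, 1:] = A[1:, 0] = 1.0
        A[1:, 1:] = K + np.eye(n) / gamma
        sol = np.linalg.lstsq(A, np.concatenate([[0.0], y]), rcond=None)[0]
        np.testing.assert_allclose(model.bias, sol[0], atol=1e-8)
        np.testing.assert_allclose(model.alphas, sol[1:], atol=1e-8)

    def test_training_response_identity(self, blobs):
        # from the stationarity conditions: f(x_i) = y_i - alpha_i / gamma
        X, y = blobs
        model = fit_lssvm(X, y, sigma=2.0, gamma=5.0)
        resp, _ = predict_lssvm(model, X)
        np.testing.assert_allclose(resp, y - model.alphas / model.gamma,
                                   atol=1e-8)

    def test_large_gamma_interpolates_separable(self, blobs):
        X, y = blobs
        model = fit_lssvm(X, y, sigma=3.0, gamma=1e6)
        resp, signs = predict_lssvm(model, X)
        np.testing.assert_array_equal(signs, y)
        np.testing.assert_allclose(resp, y, atol=1e-3)

    def test_single_point_prediction_by_kernel_sum(self):
        model = fit_lssvm(XOR_X, XOR_Y, sigma=0.7, gamma=100.0)
        x = XOR_X[2]
        expected = (rbf_kernel(x[None, :], XOR_X, 0.7)[0] @ model.alphas
                    + model.bias)
        resp, _ = predict_lssvm(model, x[None, :])
        assert resp[0] == pytest.approx(expected)

    def test_parameter_validation(self, blobs):
        X, y = blobs
        for sg, gm in [(0.0, 1.0), (1.0, 0.0)]:
            with pytest.raises(ValueError):
                fit_lssvm(X, y, sg, gm)
        with pytest.raises(ValueError, match="both"):
            fit_lssvm(X, np.ones(len(y)), 1.0, 1.0)
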