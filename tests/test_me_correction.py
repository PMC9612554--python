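"""Response/predictor corrections and corrected estimating functions."""

import numpy as np
import pytest

from boome import (
    MeasurementErrorSpec,
    MisclassificationProbabilities,
    correct_response,
    corrected_score_lr,
    corrected_score_pm,
    fit_regression_calibration,
    misclassify,
    score_lr,
    score_pm,
    sufficient_statistic,
)


class TestMisclassificationProbabilities:
    def test_singular_matrix_rejected_with_row(self):
        with pytest.raises(ValueError, match="row"):
            MisclassificationProbabilities([0.1, 0.5], [0.2, 0.5])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            MisclassificationProbabilities([1.2], [0.0])

    def test_negative_denominator_allowed(self):
        # both error rates ~0.731: the matrix is invertible with negative determinant
        p = MisclassificationProbabilities.constant(0.7311, 0.7311, 3)
        assert np.all(p.denominator < 0)


class TestCorrectResponse:
    def test_identity_without_misclassification(self):
        probs = MisclassificationProbabilities.constant(0.0, 0.0, 4)
        y = np.array([1.0, 0.0, 0.0, 1.0])
        np.testing.assert_array_equal(correct_response(y, probs), y)

    @pytest.mark.parametrize("y,expected", [(1.0, 1.2857143), (0.0, -0.1428571)])
    def test_hand_values(self, y, expected):
        probs = MisclassificationProbabilities.constant(0.1, 0.2, 1)
        assert correct_response([y], probs)[0] == pytest.approx(expected, abs=1e-6)

    def test_conditional_mean_recovers_truth(self):
        """Averaged over the misclassification channel, Y** is unbiased for Y."""
        n = 100_000
        probs = MisclassificationProbabilities.constant(0.25, 0.4, n)
        for y_true in (0.0, 1.0):
            y = np.full(n, y_true)
            y_star = misclassify(y, probs, seed=5)
            y_cc = correct_response(y_star, probs)
            assert abs(y_cc.mean() - y_true) < 0.01

    def test_conditional_mean_negative_denominator(self):
        n = 100_000
        pi = 0.7310586
        probs = MisclassificationProbabilities.constant(pi, pi, n)
        y_star = misclassify(np.ones(n), probs, seed=6)
        assert abs(correct_response(y_star, probs).mean() - 1.0) < 0.01


class TestSufficientStatistic:
    def test_zero_error_is_identity(self):
        x = np.array([1.0, 2.0])
        out = sufficient_statistic(x, 1.25, MeasurementErrorSpec(0.0), [1.0, -1.0])
        np.testing.assert_array_equal(out, x)

    def test_hand_value(self):
        out = sufficient_statistic([1.0, 2.0], 1.25, MeasurementErrorSpec(0.2), [1.0, -1.0])
        np.testing.assert_allclose(out, [1.25, 1.75], atol=1e-12)

    def test_zero_response_is_identity(self):
        x = np.array([3.0, -1.0])
        out = sufficient_statistic(x, 0.0, MeasurementErrorSpec(0.7), [2.0, 2.0])
        np.testing.assert_array_equal(out, x)


class TestRegressionCalibration:
    def test_zero_error_gives_identity_transform(self, rng):
        X = rng.standard_normal((20, 3))
        cm = fit_regression_calibration(X, MeasurementErrorSpec(0.0))
        np.testing.assert_allclose(cm.transform(X), X, atol=1e-10)

    def test_univariate_hand_value(self):
        X = np.array([[0.0], [2.0], [4.0]])
        cm = fit_regression_calibration(X, MeasurementErrorSpec(3.0))
        np.testing.assert_allclose(cm.transform(X).ravel(), [1.5, 2.0, 2.5], atol=1e-12)

    def test_mean_is_fixed_point(self, rng):
        X = rng.standard_normal((30, 4)) * 2.0 + 1.0
        cm = fit_regression_calibration(X, MeasurementErrorSpec(0.3))
        np.testing.assert_allclose(cm.transform(cm.mu_hat), cm.mu_hat, atol=1e-10)

    def test_full_matrix_matches_diagonal_on_small_p(self, rng):
        """With diagonal Sigma_eps, the coordinatewise map is Eq-equivalent to
        the full-matrix map only when the sample covariance is diagonal; on a
        diagonal-covariance population they agree asymptotically.  Here we
        check the exact algebra instead: the full map with a diagonal sample
        covariance equals the coordinatewise map."""
        X = rng.standard_normal((200, 2))
        # center, then orthogonalize, so the sample covariance is exactly diagonal
        X -= X.mean(axis=0)
        X[:, 1] -= X[:, 0] * (X[:, 0] @ X[:, 1]) / (X[:, 0] @ X[:, 0])
        me = MeasurementErrorSpec(np.array([0.2, 0.4]))
        full = fit_regression_calibration(X, me, diagonal=False)
        diag = fit_regression_calibration(X, me, diagonal=True)
        np.testing.assert_allclose(full.transform(X), diag.transform(X), atol=1e-10)

    def test_singular_covariance_full_request_raises(self, rng):
        X = rng.standard_normal((3, 10))  # p > n
        with pytest.raises(np.linalg.LinAlgError):
            fit_regression_calibration(X, MeasurementErrorSpec(0.1), diagonal=False)

    def test_p_larger_than_n_diagonal_default_works(self, rng):
        X = rng.standard_normal((5, 50))
        cm = fit_regression_calibration(X, MeasurementErrorSpec(0.1))
        assert cm.diagonal and cm.transform(X).shape == X.shape


class TestCorrectedScores:
    def test_lr_reduces_to_naive_bitwise(self, rng):
        X = rng.standard_normal((12, 4))
        Y = (rng.random(12) < 0.5).astype(float)
        beta = rng.normal(size=4)
        g_corr = corrected_score_lr(beta, X, Y, MeasurementErrorSpec(0.0))
        np.testing.assert_array_equal(g_corr, score_lr(beta, X, Y))

    def test_pm_reduces_to_naive_bitwise(self, rng):
        X = rng.standard_normal((12, 4))
        Y = (rng.random(12) < 0.5).astype(float)
        beta = rng.normal(size=4)
        np.testing.assert_array_equal(corrected_score_pm(beta, X, Y), score_pm(beta, X, Y))

    def test_lr_hand_value_at_zero_beta(self):
        g = corrected_score_lr(
            [0.0, 0.0], [[1.0, 0.0]], [1.2857143], MeasurementErrorSpec(0.2)
        )
        np.testing.assert_allclose(g, [-0.7857143, 0.0], atol=1e-6)

    def test_pm_hand_value_at_zero_beta(self):
        g = corrected_score_pm([0.0], [[1.0]], [1.2857143])
        np.testing.assert_allclose(g, [-1.2538], atol=1e-3)

    def test_lr_equals_composition(self, rng):
        """The corrected logistic score is score_lr on substituted rows/response."""
        n, p = 9, 3
        X = rng.standard_normal((n, p))
        beta = rng.normal(scale=0.3, size=p)
        me = MeasurementErrorSpec(np.array([0.1, 0.3, 0.2]))
        probs = MisclassificationProbabilities.constant(0.1, 0.2, n)
        y_star = (rng.random(n) < 0.5).astype(float)
        y_cc = correct_response(y_star, probs)
        X_ss = np.array([sufficient_statistic(X[i], y_cc[i], me, beta) for i in range(n)])
        np.testing.assert_allclose(
            corrected_score_lr(beta, X, y_cc, me), score_lr(beta, X_ss, y_cc), atol=1e-12
        )

    def test_lr_linearity_in_corrected_response(self, rng):
        """Doubling y** changes the corrected score exactly as its algebra says:
        both the response and the sufficient-statistic rows scale."""
        X = rng.standard_normal((6, 2))
        beta = rng.normal(scale=0.3, size=2)
        me = MeasurementErrorSpec(0.25)
        y = rng.normal(size=6)
        g2 = corrected_score_lr(beta, X, 2 * y, me)
        X_ss2 = X + np.outer(2 * y, me.matvec(beta))
        np.testing.assert_allclose(g2, score_lr(beta, X_ss2, 2 * y), atol=1e-12)

    def test_pm_decays_for_large_linear_predictor(self):
        g = corrected_score_pm([10.0], [[3.0]], [1.0])
        assert abs(g[0]) < 1e-10


class TestMeasurementErrorSpec:
    def test_scalar_diag_full_agree(self):
        v = np.array([1.0, -2.0, 0.5])
        s = MeasurementErrorSpec(0.3)
        d = MeasurementErrorSpec(np.full(3, 0.3))
        f = MeasurementErrorSpec(0.3 * np.eye(3))
        for spec in (s, d, f):
            np.testing.assert_allclose(spec.matvec(v), 0.3 * v, atol=1e-12)
            np.testing.assert_allclose(spec.matrix(3), 0.3 * np.eye(3), atol=1e-12)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            MeasurementErrorSpec(np.array([[1.0, 0.5], [0.0, 1.0]]))

    def test_indefinite_matrix_rejected(self):
        with pytest.raises(ValueError, match="semidefinite"):
            MeasurementErrorSpec(np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            MeasurementErrorSpec(np.full(4, 0.1)).matvec(np.ones(3))
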