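import numpy as np
import pytest

from opspls.pls import (
    explained_variance,
    fit_pls,
    predict,
    standardized_coefficients,
    wold_report,
)


def _ols_fitted(X, y):
    Xd = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    return Xd @ beta


class TestFit:
    def test_single_predictor_equals_least_squares_line(self, rng):
        x = rng.normal(size=(25, 1))
        y = 2.0 + 1.5 * x.ravel() + rng.normal(0, 0.3, 25)
        model = fit_pls(x, y, 1)
        assert np.allclose(model.fitted, _ols_fitted(x, y), atol=1e-8)

    def test_full_rank_fit_equals_ols(self, rng):
        X = rng.normal(size=(20, 6))
        y = rng.normal(size=20)
        model = fit_pls(X, y, 6)
        assert np.allclose(model.fitted, _ols_fitted(X, y), atol=1e-6)

    def test_scores_orthogonal(self, rng):
        model = fit_pls(rng.normal(size=(18, 7)), rng.normal(size=18), 5)
        G = model.scores.T @ model.scores
        off = G - np.diag(np.diag(G))
        assert np.all(np.abs(off) <= 1e-8 * np.outer(np.diag(G), np.diag(G)) ** 0.5)

    def test_training_r2_monotone_in_components(self, rng):
        X = rng.normal(size=(20, 6))
        y = rng.normal(size=20)
        r2 = []
        for a in range(1, 7):
            m = fit_pls(X, y, a)
            resid = y - m.fitted
            r2.append(1 - resid @ resid / ((y - y.mean()) @ (y - y.mean())))
        assert np.all(np.diff(r2) >= -1e-12)

    def test_matches_independent_pls_implementation(self, rng):
        """Cross-check against scikit-learn's PLS on random matrices."""
        from sklearn.cross_decomposition import PLSRegression

        for trial in range(3):
            X = rng.normal(size=(20, 8))
            y = rng.normal(size=20)
            for a in (1, 3, 5):
                ours = fit_pls(X, y, a)
                ref = PLSRegression(n_components=a, scale=True).fit(X, y)
                assert np.allclose(
                    predict(ours, X), ref.predict(X).ravel(), atol=1e-8
                )

    def test_scale_y_leaves_predictions_unchanged(self, rng):
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        a = fit_pls(X, y, 3, scale_y=False)
        b = fit_pls(X, y, 3, scale_y=True)
        assert np.allclose(a.fitted, b.fitted, atol=1e-9)
        assert np.allclose(a.coef_std, b.coef_std, atol=1e-9)

    def test_infeasible_components_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        with pytest.raises(ValueError):
            fit_pls(X, y, 5)
        with pytest.raises(ValueError):
            fit_pls(X, np.ones(10), 2)  # flat response


class TestPredict:
    def test_exact_recovery_of_noiseless_linear_response(self, rng):
        X = rng.normal(size=(20, 4))
        beta = np.array([1.0, -2.0, 0.5, 3.0])
        y = X @ beta
        model = fit_pls(X, y, 4)
        assert np.allclose(predict(model, X), y, atol=1e-6)

    def test_mean_row_predicts_mean_response(self, rng):
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        model = fit_pls(X, y, 3)
        pred = predict(model, X.mean(axis=0)[None, :])
        assert pred[0] == pytest.approx(y.mean(), abs=1e-9)

    def test_score_route_equals_coefficient_route(self, rng):
        X = rng.normal(size=(16, 5))
        y = rng.normal(size=16)
        model = fit_pls(X, y, 3)
        Xnew = rng.normal(size=(4, 5))
        via_scores = model.transform(Xnew) @ model.y_loadings + model.y_mean
        assert np.allclose(via_scores, predict(model, Xnew), atol=1e-9)

    def test_column_mismatch_rejected(self, rng):
        model = fit_pls(rng.normal(size=(10, 3)), rng.normal(size=10), 2)
        with pytest.raises(ValueError):
            predict(model, rng.normal(size=(2, 4)))


class TestCoefficients:
    def test_reference_model_significance_pattern(self):
        """Half-maximum rule on the published standardized coefficients."""
        names = ["EEig02r", "SOFT", "alpha_xx", "q10NBO", "q2NBO", "SsssN(oth)"]
        b = np.array([-0.549, 0.545, 0.377, 0.238, 0.250, -0.314])
        report = wold_report(b, names)
        assert report.threshold == pytest.approx(0.2745, abs=1e-12)
        flagged = {n for n, s in zip(report.names, report.significant) if s}
        assert flagged == {"EEig02r", "SOFT", "alpha_xx", "SsssN(oth)"}
        assert not report.significant[names.index("q10NBO")]
        assert not report.significant[names.index("q2NBO")]

    def test_single_descriptor_always_significant(self):
        report = wold_report(np.array([0.1]), ["only"])
        assert report.significant.all()

    def test_equal_magnitudes_all_significant(self):
        report = wold_report(np.array([0.4, -0.4, 0.4]), list("abc"))
        assert report.significant.all()

    def test_model_standardized_coefficients_definition(self, rng):
        X = rng.normal(size=(20, 4)) * np.array([1.0, 10.0, 0.1, 5.0])
        y = rng.normal(size=20)
        model = fit_pls(X, y, 3)
        expected = model.coef_raw * X.std(axis=0, ddof=1) / y.std(ddof=1)
        report = standardized_coefficients(model)
        assert np.allclose(report.b_std, expected, atol=1e-10)


class TestExplainedVariance:
    def test_full_rank_cumulates_to_everything(self, rng):
        X = rng.normal(size=(12, 4))
        y = rng.normal(size=12)
        model = fit_pls(X, y, 4)
        ev = explained_variance(model)
        assert np.all(ev >= 0)
        assert ev.sum() == pytest.approx(100.0, abs=1e-6)

    def test_orthonormal_design_single_component_share(self, rng):
        """With orthonormal autoscaled columns and y loading equally on all,
        the first latent variable captures exactly 1/m of the X variance."""
        n, m = 20, 5
        A = rng.normal(size=(n, m))
        A -= A.mean(axis=0)
        Q, _ = np.linalg.qr(A)
        X = Q * np.sqrt(n - 1)  # unit sample sd, mutually orthogonal, centred
        y = X.sum(axis=1)
        model = fit_pls(X, y, 1)
        assert model.explained_x_variance[0] == pytest.approx(100.0 / m, abs=1e-8)

    def test_cumulative_never_exceeds_total(self, rng):
        model = fit_pls(rng.normal(size=(15, 8)), rng.normal(size=15), 6)
        ev = model.explained_x_variance
        assert np.all(ev >= 0) and ev.sum() <= 100 + 1e-6
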