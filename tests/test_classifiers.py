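import numpy as np
import pytest
from scipy.optimize import minimize

from ftirprint.classifiers import (
    cv_accuracy_svm,
    decision_values_binary,
    dual_objective_binary,
    fit_pca_lda,
    fit_svm_rbf,
    mahalanobis_distances,
    pair_support_vectors,
    predict_pca_lda,
    predict_svm,
    tune_svm,
)
from ftirprint.chemometrics_core import project_pca
from ftirprint.validation import venetian_blinds


def two_gaussians(rng, n=50, sep=10.0, dim=4):
    a = rng.normal(size=(n, dim))
    b = rng.normal(size=(n, dim))
    b[:, 0] += sep
    X = np.vstack([a, b])
    y = np.array(["A"] * n + ["B"] * n)
    return X - X.mean(axis=0), y


# ---------------------------------------------------------------------------
# PCA-LDA
# ---------------------------------------------------------------------------

class TestPcaLda:
    def test_separated_gaussians_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        X, y = two_gaussians(rng, n=50, sep=10.0)
        m = fit_pca_lda(X, y, n_pcs=3)
        pred, _ = predict_pca_lda(m, X)
        assert np.mean(pred == y) == 1.0

    def test_no_signal_accuracy_near_chance(self):
        rng = np.random.default_rng(1)
        n = 150
        X = rng.normal(size=(2 * n, 5))
        X -= X.mean(axis=0)
        y = np.array(["A"] * n + ["B"] * n)
        m = fit_pca_lda(X, y, n_pcs=4)
        pred, _ = predict_pca_lda(m, X)
        acc = np.mean(pred == y)
        se = np.sqrt(0.25 / (2 * n))
        assert abs(acc - 0.5) <= 3 * se + 0.05  # training optimism allowance

    def test_matches_brute_force_mahalanobis_oracle(self):
        rng = np.random.default_rng(2)
        n = 15
        X = np.vstack(
            [rng.normal(loc=c, size=(n, 4)) for c in ([0, 0, 0, 0], [2, 0, 1, 0], [0, 3, 0, 1])]
        )
        X -= X.mean(axis=0)
        y = np.repeat(["a", "b", "c"], n)
        m = fit_pca_lda(X, y, n_pcs=2)
        scores = project_pca(m.pca, X)
        # brute force: explicit pooled-covariance Mahalanobis distances
        Sinv = np.linalg.inv(m.pooled_cov)
        expected = []
        for s in scores:
            d2 = [ (s - mu) @ Sinv @ (s - mu) for mu in m.class_means ]
            expected.append(m.classes[int(np.argmin(d2))])
        pred, _ = predict_pca_lda(m, X)
        assert list(pred) == expected

    def test_point_at_class_mean_gets_that_class(self):
        rng = np.random.default_rng(3)
        X, y = two_gaussians(rng, n=30, sep=6.0)
        m = fit_pca_lda(X, y, n_pcs=2)
        # invert the PCA projection of the class mean back to input space
        x_at_mean = m.class_means[1] @ m.pca.loadings.T + m.pca.mean
        pred, _ = predict_pca_lda(m, x_at_mean[None, :])
        assert pred[0] == m.classes[1]

    def test_equidistant_tie_breaks_to_first_class(self):
        # construct a model with perfectly symmetric class means so the
        # origin is exactly equidistant from both
        from ftirprint.chemometrics_core import PcaModel
        from ftirprint.classifiers import PcaLdaModel

        pca = PcaModel(
            mean=np.zeros(2),
            loadings=np.eye(2),
            scores=np.zeros((2, 2)),
            explained_variance_pct=np.array([60.0, 40.0]),
            k=2,
        )
        m = PcaLdaModel(
            pca=pca,
            class_means=np.array([[-1.0, 0.0], [1.0, 0.0]]),
            pooled_cov=np.eye(2),
            pooled_cov_inv=np.eye(2),
            canonical_directions=np.array([[1.0], [0.0]]),
            classes=np.array(["A", "B"]),
            priors=np.array([0.5, 0.5]),
        )
        d2 = mahalanobis_distances(m, np.zeros((1, 2)))
        assert d2[0, 0] == d2[0, 1]
        pred, _ = predict_pca_lda(m, np.zeros((1, 2)))
        assert pred[0] == "A"

    def test_fit_predict_consistency(self):
        rng = np.random.default_rng(5)
        X, y = two_gaussians(rng, n=25, sep=3.0)
        m = fit_pca_lda(X, y, n_pcs=3)
        p1, _ = predict_pca_lda(m, X)
        p2, _ = predict_pca_lda(m, X)
        assert np.array_equal(p1, p2)

    def test_canonical_scores_shape(self):
        rng = np.random.default_rng(6)
        n = 20
        X = rng.normal(size=(3 * n, 6))
        X -= X.mean(axis=0)
        y = np.repeat(["a", "b", "c"], n)
        m = fit_pca_lda(X, y, n_pcs=5)
        _, canon = predict_pca_lda(m, X)
        assert canon.shape == (3 * n, 2)

    def test_affine_scale_invariance_of_predictions(self):
        # scaling all PC scores is absorbed by the pooled covariance
        rng = np.random.default_rng(7)
        X, y = two_gaussians(rng, n=30, sep=2.0)
        m = fit_pca_lda(X, y, n_pcs=3)
        pred1, _ = predict_pca_lda(m, X)
        m2 = fit_pca_lda(X * 7.5, y, n_pcs=3)
        pred2, _ = predict_pca_lda(m2, X * 7.5)
        assert np.array_equal(pred1, pred2)

    def test_validation_errors(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError):
            fit_pca_lda(X, np.array(["a"] * 10), n_pcs=2)
        y = np.array(["a"] * 5 + ["b"] * 5)
        with pytest.raises(ValueError):
            fit_pca_lda(X, y, n_pcs=0)


# ---------------------------------------------------------------------------
# SVM
# ---------------------------------------------------------------------------

class TestSvmFit:
    def test_separable_kkt_margins(self):
        rng = np.random.default_rng(10)
        X, y = two_gaussians(rng, n=25, sep=12.0)
        m = fit_svm_rbf(X, y, cost=1e4, gamma=0.1, probability=False)
        pred, _ = predict_svm(m, X)
        assert np.mean(pred == y) == 1.0
        dv = decision_values_binary(m, m.support_vectors)
        free = np.abs(m.dual_coefs[0]) < 1e4 * (1 - 1e-6)
        np.testing.assert_allclose(np.abs(dv[free]), 1.0, atol=1e-3)

    def test_xor_pattern_separated_by_rbf(self):
        base = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        X = np.repeat(base, 10, axis=0) + np.random.default_rng(11).normal(
            scale=0.05, size=(40, 2)
        )
        y = np.repeat(["A", "A", "B", "B"], 10)
        m = fit_svm_rbf(X, y, cost=10.0, gamma=1.0, probability=False)
        pred, _ = predict_svm(m, X)
        assert np.mean(pred == y) == 1.0

    def test_dual_objective_matches_qp_oracle(self):
        rng = np.random.default_rng(12)
        n = 15
        X = np.vstack([rng.normal(size=(n, 2)), rng.normal(loc=1.5, size=(n, 2))])
        labels = np.array(["A"] * n + ["B"] * n)
        C, gamma = 2.0, 0.5
        m = fit_svm_rbf(X, labels, cost=C, gamma=gamma, probability=False)
        impl_obj = dual_objective_binary(m, X, labels)

        # dense QP oracle: maximize sum(a) - 0.5 a^T (yy' * K) a
        y = np.where(labels == "A", -1.0, 1.0)  # libsvm: first class negative? sign-free objective
        d2 = (
            np.sum(X**2, axis=1)[:, None]
            + np.sum(X**2, axis=1)[None, :]
            - 2 * X @ X.T
        )
        K = np.exp(-gamma * d2)
        Q = (y[:, None] * y[None, :]) * K

        def neg_obj(a):
            return -(a.sum() - 0.5 * a @ Q @ a)

        def neg_obj_grad(a):
            return -(np.ones_like(a) - Q @ a)

        cons = {"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}
        res = minimize(
            neg_obj,
            np.full(2 * n, C / 2),
            jac=neg_obj_grad,
            bounds=[(0, C)] * 2 * n,
            constraints=[cons],
            method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-12},
        )
        assert res.success
        oracle_obj = -res.fun
        assert abs(impl_obj - oracle_obj) <= 1e-4 * abs(oracle_obj)

    def test_dual_coef_bounded_by_cost(self):
        rng = np.random.default_rng(13)
        X, y = two_gaussians(rng, n=40, sep=1.0)
        m = fit_svm_rbf(X, y, cost=3.0, gamma=0.5, probability=False)
        assert np.all(np.abs(m.dual_coefs) <= 3.0 + 1e-9)
        assert m.n_sv == m.support_vectors.shape[0]

    def test_invalid_hyperparameters(self):
        with pytest.raises(ValueError):
            fit_svm_rbf(np.zeros((4, 2)), np.array(["a", "a", "b", "b"]), cost=-1)
        with pytest.raises(ValueError):
            fit_svm_rbf(np.zeros((4, 2)), np.array(["a", "a", "b", "b"]), gamma=0)

    def test_decision_depends_only_on_support_vectors(self):
        rng = np.random.default_rng(14)
        X, y = two_gaussians(rng, n=60, sep=8.0)
        m = fit_svm_rbf(X, y, cost=10.0, gamma=0.5, probability=False, tol=1e-9)
        sv_idx = m._svc.support_
        keep = np.zeros(len(y), dtype=bool)
        keep[sv_idx] = True
        m2 = fit_svm_rbf(
            X[keep], y[keep], cost=10.0, gamma=0.5, probability=False, tol=1e-9
        )
        grid = rng.normal(size=(50, X.shape[1]))
        d1 = decision_values_binary(m, grid)
        d2 = decision_values_binary(m2, grid)
        np.testing.assert_allclose(d1, d2, atol=1e-6)


class TestSvmPredict:
    def test_probability_rows_sum_to_one(self):
        rng = np.random.default_rng(15)
        n = 30
        X = np.vstack(
            [rng.normal(loc=c, size=(n, 3)) for c in ([0, 0, 0], [4, 0, 0], [0, 4, 0])]
        )
        y = np.repeat(["a", "b", "c"], n)
        m = fit_svm_rbf(X, y, cost=10.0, gamma=0.3)
        far = rng.normal(loc=50.0, size=(5, 3))
        _, proba = predict_svm(m, np.vstack([X, far]))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_true_class_probability_dominates_on_separable_data(self):
        rng = np.random.default_rng(16)
        X, y = two_gaussians(rng, n=60, sep=8.0)
        m = fit_svm_rbf(X, y, cost=10.0, gamma=0.5)
        _, proba = predict_svm(m, X)
        true_idx = np.array([list(m.classes).index(c) for c in y])
        frac = np.mean(proba[np.arange(len(y)), true_idx] > 0.5)
        assert frac >= 0.95

    def test_argmax_probability_agrees_with_vote(self):
        rng = np.random.default_rng(17)
        n = 40
        X = np.vstack(
            [rng.normal(loc=c, size=(n, 3)) for c in ([0, 0, 0], [5, 0, 0], [0, 5, 0])]
        )
        y = np.repeat(["a", "b", "c"], n)
        m = fit_svm_rbf(X, y, cost=10.0, gamma=0.3)
        labels, proba = predict_svm(m, X)
        agree = np.mean(m.classes[np.argmax(proba, axis=1)] == labels)
        assert agree >= 0.99

    def test_dimension_mismatch(self):
        rng = np.random.default_rng(18)
        X, y = two_gaussians(rng, n=10, sep=5.0)
        m = fit_svm_rbf(X, y, probability=False)
        with pytest.raises(ValueError):
            predict_svm(m, np.zeros((2, X.shape[1] + 1)))

    def test_degenerate_single_class_input(self):
        rng = np.random.default_rng(19)
        X, y = two_gaussians(rng, n=20, sep=6.0)
        m = fit_svm_rbf(X, y, cost=10.0, gamma=0.5)
        labels, proba = predict_svm(m, X[:5])
        assert set(labels) <= set(m.classes)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)


class TestPairSupportVectors:
    def test_binary_pair_recovers_all_svs(self):
        rng = np.random.default_rng(20)
        X, y = two_gaussians(rng, n=30, sep=2.0)
        m = fit_svm_rbf(X, y, cost=1.0, gamma=0.5, probability=False)
        rows_a, coefs_a = pair_support_vectors(m, "A", "B")
        rows_b, coefs_b = pair_support_vectors(m, "B", "A")
        assert rows_a.shape[0] + rows_b.shape[0] == m.n_sv
        # the two classes carry opposite-signed coefficients in the subproblem
        assert len(set(np.sign(coefs_a))) == 1
        assert len(set(np.sign(coefs_b))) == 1
        assert np.sign(coefs_a[0]) == -np.sign(coefs_b[0])

    def test_multiclass_pair_extraction_consistent_with_refit(self):
        rng = np.random.default_rng(21)
        n = 25
        X = np.vstack(
            [rng.normal(loc=c, size=(n, 2)) for c in ([0, 0], [3, 0], [0, 3])]
        )
        y = np.repeat(["a", "b", "c"], n)
        m = fit_svm_rbf(X, y, cost=5.0, gamma=0.5, probability=False)
        rows_a, _ = pair_support_vectors(m, "a", "b")
        # oracle: a dedicated binary fit on the same pair finds the same SVs
        mask = np.isin(y, ["a", "b"])
        mb = fit_svm_rbf(X[mask], y[mask], cost=5.0, gamma=0.5, probability=False)
        rows_a2 = mb.support_vectors[mb.sv_class_labels == "a"]
        set_a = {tuple(np.round(r, 9)) for r in rows_a}
        set_a2 = {tuple(np.round(r, 9)) for r in rows_a2}
        assert set_a == set_a2


class TestTuneSvm:
    def test_single_point_grid(self):
        rng = np.random.default_rng(22)
        X, y = two_gaussians(rng, n=20, sep=5.0)
        folds = venetian_blinds(len(y), 4)
        c, g, acc = tune_svm(X, y, [2.0], [0.5], folds)
        assert (c, g) == (2.0, 0.5)
        assert 0 <= acc <= 1

    def test_selected_pair_is_exhaustively_best(self):
        rng = np.random.default_rng(23)
        X, y = two_gaussians(rng, n=25, sep=4.0)
        folds = venetian_blinds(len(y), 5)
        cost_grid, gamma_grid = [0.1, 10.0], [0.05, 0.5]
        c, g, acc = tune_svm(X, y, cost_grid, gamma_grid, folds)
        # oracle: re-evaluate every grid point independently
        for cc in cost_grid:
            for gg in gamma_grid:
                other = cv_accuracy_svm(X, y, folds, cc, gg)
                assert acc >= other - 1e-12

    def test_printed_settings_expressible_on_log_grid(self):
        cost_grid = 10.0 ** np.arange(-2, 3)  # includes 10
        gamma_grid = 10.0 ** (np.arange(-4, 5) / 2.0)  # includes 10**0.5 = 3.16
        assert 10.0 in cost_grid
        assert np.any(np.isclose(gamma_grid, 10**0.5))
        assert np.isclose(round(10**0.5, 2), 3.16)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            tune_svm(np.zeros((8, 2)), np.array(["a", "b"] * 4), [], [1.0],
                     venetian_blinds(8, 2))


def test_gamma_to_zero_approaches_linear_ordering():
    # with gamma -> 0 the RBF decision ordering matches a linear classifier's
    rng = np.random.default_rng(24)
    X, y = two_gaussians(rng, n=30, sep=3.0, dim=2)
    w_dir = X[y == "B"].mean(axis=0) - X[y == "A"].mean(axis=0)
    grid = rng.normal(size=(40, 2)) * 2
    linear_scores = grid @ w_dir
    from scipy.stats import spearmanr

    corrs = []
    for gamma in (1.0, 0.1, 0.001):
        m = fit_svm_rbf(X, y, cost=10.0, gamma=gamma, probability=False)
        dv = decision_values_binary(m, grid)
        corrs.append(abs(spearmanr(linear_scores, dv).statistic))
    assert corrs[-1] >= corrs[0] - 1e-9
    assert corrs[-1] > 0.9
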