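"""PCA-LDA and RBF-SVM classifiers.

PCA-LDA classifies by minimum Mahalanobis distance to class means in a
truncated principal-component space, under a pooled within-class covariance
and equal priors; canonical directions from the between/within generalized
eigenproblem support scores plots.

The soft-margin SVM dual is solved by libsvm (via scikit-learn) with the
kernel K(x, y) = exp(-gamma * ||x - y||^2); the fitted state (support
vectors, dual coefficients, intercepts, Platt sigmoid parameters) is
re-exposed in a documented layout so downstream biomarker extraction can
address the per-pair subproblems directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from sklearn.svm import SVC

from ftirprint.chemometrics_core import PcaModel, fit_pca, project_pca
from ftirprint.validation import FoldAssignment


# ---------------------------------------------------------------------------
# PCA-LDA
# ---------------------------------------------------------------------------

@dataclass
class PcaLdaModel:
    pca: PcaModel
    class_means: np.ndarray  # (n_classes, k) in PC space
    pooled_cov: np.ndarray  # (k, k)
    pooled_cov_inv: np.ndarray
    canonical_directions: np.ndarray  # (k, n_classes - 1)
    classes: np.ndarray
    priors: np.ndarray


def fit_pca_lda(
    X_train: np.ndarray,
    labels: np.ndarray,
    n_pcs: int,
    ridge_eps: float = 1e-8,
    cond_limit: float = 1e10,
) -> PcaLdaModel:
    """Fit LDA on the first ``n_pcs`` PCA scores of centered training data."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if n_pcs < classes.size - 1:
        raise ValueError("n_pcs must be at least n_classes - 1")
    pca = fit_pca(np.asarray(X_train, dtype=float), n_pcs)
    T = pca.scores
    k = T.shape[1]
    n = T.shape[0]
    means = np.zeros((classes.size, k))
    Sw = np.zeros((k, k))
    for i, c in enumerate(classes):
        Tc = T[labels == c]
        if Tc.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 training rows")
        means[i] = Tc.mean(axis=0)
        d = Tc - means[i]
        Sw += d.T @ d
    pooled = Sw / (n - classes.size)
    if np.linalg.cond(pooled) > cond_limit:
        warnings.warn("pooled covariance ill-conditioned; ridge applied", stacklevel=2)
        pooled = pooled + ridge_eps * np.trace(pooled) / k * np.eye(k)
    pooled_inv = np.linalg.inv(pooled)
    # between-class scatter (equal priors: unweighted over class means)
    gmean = means.mean(axis=0)
    Sb = np.zeros((k, k))
    for i in range(classes.size):
        d = means[i] - gmean
        Sb += np.outer(d, d)
    evals, evecs = eigh(Sb, pooled)
    order = np.argsort(evals)[::-1]
    n_canon = classes.size - 1
    canon = evecs[:, order[:n_canon]]
    for j in range(canon.shape[1]):
        col = canon[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            canon[:, j] = -col
    priors = np.full(classes.size, 1.0 / classes.size)
    return PcaLdaModel(
        pca=pca,
        class_means=means,
        pooled_cov=pooled,
        pooled_cov_inv=pooled_inv,
        canonical_directions=canon,
        classes=classes,
        priors=priors,
    )


def mahalanobis_distances(m: PcaLdaModel, scores: np.ndarray) -> np.ndarray:
    """(n, n_classes) squared Mahalanobis distances to each class mean."""
    out = np.empty((scores.shape[0], m.classes.size))
    for i in range(m.classes.size):
        d = scores - m.class_means[i]
        out[:, i] = np.einsum("ij,jk,ik->i", d, m.pooled_cov_inv, d)
    return out


def predict_pca_lda(
    m: PcaLdaModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Labels by minimum Mahalanobis distance, plus canonical scores.

    ``X`` must be centered by the same mean as the training matrix.
    Distance ties resolve to the first class in label order.
    """
    scores = project_pca(m.pca, X)
    d2 = mahalanobis_distances(m, scores)
    labels = m.classes[np.argmin(d2, axis=1)]
    canonical = scores @ m.canonical_directions
    return labels, canonical


# ---------------------------------------------------------------------------
# RBF SVM
# ---------------------------------------------------------------------------

@dataclass
class SvmModel:
    cost: float
    gamma: float
    classes: np.ndarray
    support_vectors: np.ndarray  # unique SV rows, training order
    dual_coefs: np.ndarray  # packed one-vs-one layout, (n_classes-1, n_sv)
    intercepts: np.ndarray  # per-pair, pairs (i, j) with i < j in class order
    sv_class_labels: np.ndarray  # class of each stored SV
    n_sv: int
    platt_params: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    _svc: SVC | None = None

    @property
    def n_support_per_class(self) -> np.ndarray:
        return np.array(
            [(self.sv_class_labels == c).sum() for c in self.classes]
        )


def fit_svm_rbf(
    X_train: np.ndarray,
    labels: np.ndarray,
    cost: float = 10.0,
    gamma: float = 3.16,
    probability: bool = True,
    random_state: int = 0,
    tol: float = 1e-3,
) -> SvmModel:
    """Fit a one-vs-one soft-margin RBF SVM.

    Platt sigmoid parameters for class probabilities are fitted on internally
    cross-validated decision values (libsvm's procedure).
    """
    if cost <= 0 or gamma <= 0:
        raise ValueError("cost and gamma must be positive")
    X_train = np.asarray(X_train, dtype=float)
    labels = np.asarray(labels)
    with warnings.catch_warnings():
        # scikit-learn >= 1.9 deprecates SVC(probability=True); libsvm's
        # Platt-on-CV-decision-values procedure is exactly what we want
        warnings.simplefilter("ignore", FutureWarning)
        svc = SVC(
            C=cost,
            kernel="rbf",
            gamma=gamma,
            probability=probability,
            random_state=random_state,
            tol=tol,
            cache_size=200,
        )
        svc.fit(X_train, labels)
        sv_classes = np.repeat(svc.classes_, svc.n_support_)
        platt = (
            np.column_stack([svc.probA_, svc.probB_])
            if probability
            else np.empty((0, 2))
        )
    return SvmModel(
        cost=cost,
        gamma=gamma,
        classes=svc.classes_,
        support_vectors=svc.support_vectors_,
        dual_coefs=svc.dual_coef_,
        intercepts=svc.intercept_,
        sv_class_labels=sv_classes,
        n_sv=svc.support_vectors_.shape[0],
        platt_params=platt,
        _svc=svc,
    )


def predict_svm(m: SvmModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels (one-vs-one vote) and class probabilities.

    Probability rows sum to 1; columns follow ``m.classes`` order.
    """
    if m._svc is None:
        raise ValueError("model lacks its fitted solver state")
    X = np.asarray(X, dtype=float)
    if X.shape[1] != m.support_vectors.shape[1]:
        raise ValueError(
            f"dimension mismatch: {X.shape[1]} columns vs "
            f"{m.support_vectors.shape[1]} expected"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        labels = m._svc.predict(X)
        if m.platt_params.size:
            proba = m._svc.predict_proba(X)
        else:
            proba = np.full((X.shape[0], m.classes.size), 1.0 / m.classes.size)
    return labels, proba


def pair_support_vectors(
    m: SvmModel, class_a, class_b
) -> tuple[np.ndarray, np.ndarray]:
    """Support vectors of ``class_a`` active in the (class_a, class_b) pair.

    Returns (rows, coefficients). In the packed one-vs-one layout, the
    coefficient of an SV of class c against class o sits in row
    ``o - (o > c)`` of ``dual_coefs``.
    """
    classes = list(m.classes)
    a, b = classes.index(class_a), classes.index(class_b)
    if a == b:
        raise ValueError("classes must differ")
    row = b - 1 if b > a else b
    in_a = m.sv_class_labels == m.classes[a]
    coefs = m.dual_coefs[row, in_a]
    active = coefs != 0
    return m.support_vectors[in_a][active], coefs[active]


def decision_values_binary(m: SvmModel, X: np.ndarray) -> np.ndarray:
    """Decision function of a two-class model (positive => first class...).

    Exposed for margin/KKT diagnostics on binary fits.
    """
    if m.classes.size != 2:
        raise ValueError("decision_values_binary requires a 2-class model")
    return m._svc.decision_function(np.asarray(X, dtype=float))


def dual_objective_binary(
    m: SvmModel, X_train: np.ndarray, labels: np.ndarray
) -> float:
    """Value of the soft-margin dual objective for a fitted 2-class model.

    obj = sum(alpha) - 1/2 * sum_ij alpha_i alpha_j y_i y_j K(x_i, x_j),
    computed from the stored dual coefficients (which carry y * alpha).
    """
    if m.classes.size != 2:
        raise ValueError("dual objective helper requires a 2-class model")
    ya = m.dual_coefs[0]  # y_i * alpha_i over SVs
    sv = m.support_vectors
    d2 = (
        np.sum(sv**2, axis=1)[:, None]
        + np.sum(sv**2, axis=1)[None, :]
        - 2 * sv @ sv.T
    )
    K = np.exp(-m.gamma * d2)
    return float(np.sum(np.abs(ya)) - 0.5 * ya @ K @ ya)


def tune_svm(
    X: np.ndarray,
    labels: np.ndarray,
    cost_grid: np.ndarray,
    gamma_grid: np.ndarray,
    cv: FoldAssignment,
) -> tuple[float, float, float]:
    """Exhaustive grid search maximizing cross-validated accuracy.

    Ties resolve toward the smaller cost, then the smaller gamma.
    Returns (best cost, best gamma, best CV accuracy as a fraction).
    """
    cost_grid = np.sort(np.asarray(cost_grid, dtype=float))
    gamma_grid = np.sort(np.asarray(gamma_grid, dtype=float))
    if cost_grid.size == 0 or gamma_grid.size == 0:
        raise ValueError("empty hyperparameter grid")
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    folds = cv.fold_index
    best = (-1.0, None, None)
    for c in cost_grid:
        for g in gamma_grid:
            correct = 0
            for f in range(cv.k):
                test = folds == f
                train = ~test
                model = fit_svm_rbf(
                    X[train], labels[train], cost=c, gamma=g, probability=False
                )
                pred, _ = predict_svm(model, X[test])
                correct += int((pred == labels[test]).sum())
            acc = correct / labels.size
            if acc > best[0]:
                best = (acc, c, g)
    return best[1], best[2], best[0]


def cv_accuracy_svm(
    X: np.ndarray,
    labels: np.ndarray,
    cv: FoldAssignment,
    cost: float,
    gamma: float,
) -> float:
    """Venetian-blinds cross-validated accuracy at fixed hyperparameters."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    correct = 0
    for f in range(cv.k):
        test = cv.fold_index == f
        train = ~test
        model = fit_svm_rbf(
            X[train], labels[train], cost=cost, gamma=gamma, probability=False
        )
        pred, _ = predict_svm(model, X[test])
        correct += int((pred == labels[test]).sum())
    return correct / labels.size
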