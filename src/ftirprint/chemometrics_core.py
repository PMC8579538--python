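"""Principal component analysis and PLS1 regression engines.

PCA is computed by singular value decomposition with a deterministic sign
convention (largest-magnitude loading element positive). PLS1 uses the
NIPALS sequence of latent variables; latent-variable count is selected by
cross-validated RMSE with a parsimony tie-break.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class PcaModel:
    """Fitted principal component decomposition."""

    mean: np.ndarray
    loadings: np.ndarray  # (n_points, k), orthonormal columns
    scores: np.ndarray  # (n_train, k)
    explained_variance_pct: np.ndarray  # length k, percent scale
    k: int
    singular_values: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class PlsModel:
    """Fitted PLS1 regression model."""

    n_lv: int
    x_weights: np.ndarray  # (n_points, n_lv)
    x_loadings: np.ndarray  # (n_points, n_lv)
    y_loadings: np.ndarray  # (n_lv,)
    regression_vector: np.ndarray  # (n_points,)
    x_mean: np.ndarray
    y_mean: float
    cv_rmse_per_lv: np.ndarray = field(default_factory=lambda: np.array([]))

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean) @ self.regression_vector + self.y_mean


def fit_pca(X: np.ndarray, k: int, *, center: bool = False) -> PcaModel:
    """PCA of ``X`` via SVD.

    ``X`` is expected to be column-centered already (the pipeline centers by
    the training mean before calling); a warning is issued otherwise.
    With ``center=True`` the mean is removed here and stored on the model.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if center:
        mean = X.mean(axis=0)
        Xc = X - mean
    else:
        mean = np.zeros(p)
        Xc = X
        col_means = np.abs(X.mean(axis=0))
        if col_means.max() > 1e-8:
            warnings.warn(
                "fit_pca input does not look centered "
                f"(max |column mean| = {col_means.max():.3g})",
                stacklevel=2,
            )
    max_k = min(n - 1, p) if n > 1 else 1
    if k > max_k:
        raise ValueError(f"k={k} exceeds the maximum of {max_k} components")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # truncate to numerical rank
    tol = s[0] * max(n, p) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    k_eff = min(k, max(rank, 1))
    total_var = float(np.sum(s**2))
    ev_pct = (
        100.0 * s[:k_eff] ** 2 / total_var if total_var > 0 else np.zeros(k_eff)
    )
    loadings = Vt[:k_eff].T.copy()
    # sign convention: largest-magnitude element of each loading is positive
    for j in range(k_eff):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
    scores = Xc @ loadings
    return PcaModel(
        mean=mean,
        loadings=loadings,
        scores=scores,
        explained_variance_pct=ev_pct,
        k=k_eff,
        singular_values=s[:k_eff].copy(),
    )


def project_pca(m: PcaModel, X_new: np.ndarray) -> np.ndarray:
    """Scores of new rows: (X_new - mean) @ loadings."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[-1] != m.loadings.shape[0]:
        raise ValueError(
            f"dimension mismatch: data has {X_new.shape[-1]} columns, "
            f"model expects {m.loadings.shape[0]}"
        )
    return (X_new - m.mean) @ m.loadings


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    """Sequential NIPALS latent variables on centered data."""
    n, p = Xc.shape
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    Xr, yr = Xc.copy(), yc.copy()
    for a in range(n_lv):
        w = Xr.T @ yr
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            # residual X carries no covariance with y; stop early
            W, P, q = W[:, :a], P[:, :a], q[:a]
            break
        w /= nw
        t = Xr @ w
        tt = float(t @ t)
        if tt < 1e-300:
            W, P, q = W[:, :a], P[:, :a], q[:a]
            break
        p_a = Xr.T @ t / tt
        q_a = float(yr @ t / tt)
        W[:, a], P[:, a], q[a] = w, p_a, q_a
        Xr = Xr - np.outer(t, p_a)
        yr = yr - q_a * t
    return W, P, q


def _regression_vector(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    if W.shape[1] == 0:
        return np.zeros(W.shape[0])
    # b = W (P^T W)^-1 q
    return W @ np.linalg.solve(P.T @ W, q)


def fit_pls1(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    cv: np.ndarray | None = None,
) -> PlsModel:
    """Fit a single-response PLS regression with ``n_lv`` latent variables.

    If a fold assignment ``cv`` is supplied, ``cv_rmse_per_lv`` holds the
    cross-validated RMSE for 1..n_lv latent variables.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size != X.shape[0]:
        raise ValueError("y must be a vector with one entry per row of X")
    if np.ptp(y) == 0:
        raise ValueError("constant response: PLS1 is degenerate")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q = _nipals_pls1(X - x_mean, y - y_mean, n_lv)
    model = PlsModel(
        n_lv=W.shape[1],
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        regression_vector=_regression_vector(W, P, q),
        x_mean=x_mean,
        y_mean=y_mean,
    )
    if cv is not None:
        model.cv_rmse_per_lv = cv_rmse_curve(X, y, n_lv, cv)
    return model


def cv_rmse_curve(
    X: np.ndarray, y: np.ndarray, max_lv: int, folds: np.ndarray
) -> np.ndarray:
    """Cross-validated RMSE for PLS1 with 1..max_lv latent variables."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    folds = np.asarray(folds)
    press = np.zeros(max_lv)
    for f in np.unique(folds):
        test = folds == f
        train = ~test
        x_mean = X[train].mean(axis=0)
        y_mean = float(y[train].mean())
        if np.ptp(y[train]) == 0:
            pred = np.full((max_lv, int(test.sum())), y_mean)
        else:
            W, P, q = _nipals_pls1(X[train] - x_mean, y[train] - y_mean, max_lv)
            pred = np.empty((max_lv, int(test.sum())))
            for a in range(max_lv):
                a_eff = min(a + 1, W.shape[1])
                b = _regression_vector(W[:, :a_eff], P[:, :a_eff], q[:a_eff])
                pred[a] = (X[test] - x_mean) @ b + y_mean
        press += np.sum((pred - y[test]) ** 2, axis=1)
    return np.sqrt(press / y.size)


def select_n_lv(
    X: np.ndarray, y: np.ndarray, max_lv: int, cv: np.ndarray
) -> int:
    """Latent-variable count minimizing CV RMSE; ties resolved to fewer LVs."""
    if max_lv < 1:
        raise ValueError("max_lv must be at least 1")
    rmse = cv_rmse_curve(X, y, max_lv, cv)
    best = int(np.argmin(rmse))  # argmin returns the first (smallest) index
    # treat near-equal RMSE as a tie in favour of parsimony
    for a in range(best):
        if rmse[a] <= rmse[best] * (1 + 1e-9):
            return a + 1
    return best + 1


def cv_r2(X: np.ndarray, y: np.ndarray, n_lv: int, folds: np.ndarray) -> float:
    """Cross-validated R^2 (Q^2) of a PLS1 model with ``n_lv`` LVs."""
    rmse = cv_rmse_curve(X, y, n_lv, folds)[n_lv - 1]
    ss_tot = float(np.sum((y - np.mean(y)) ** 2)) / y.size
    if ss_tot == 0:
        return 0.0
    return 1.0 - rmse**2 / ss_tot
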