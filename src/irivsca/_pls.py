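"""Lean univariate SIMPLS kernel and cross-validated RMSE.

The IRIV screen evaluates thousands of small PLS sub-models per round, so
the inner loop uses this minimal NumPy implementation of SIMPLS (de Jong,
1993) for a single response. For a univariate response it spans the same
Krylov subspace as NIPALS PLS1, so predictions agree with
``sklearn.cross_decomposition.PLSRegression`` to numerical precision (the
test suite checks this); sklearn remains the user-facing PLSR estimator.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def pls_coefficients(X: np.ndarray, y: np.ndarray, n_components: int):
    """Fit univariate SIMPLS, returning (coef, x_mean, y_mean).

    Predictions are ``(Xnew - x_mean) @ coef + y_mean``. Components beyond
    the effective rank are dropped silently.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean

    a_max = min(n_components, p, n - 1)
    s = Xc.T @ yc  # p-vector of covariances
    R = np.empty((p, a_max))
    q = np.empty(a_max)
    V = np.empty((p, a_max))
    a = 0
    for a in range(a_max):
        r = s.copy()
        t = Xc @ r
        norm_t = np.linalg.norm(t)
        if norm_t < _EPS or np.linalg.norm(r) < _EPS:
            break
        t /= norm_t
        r /= norm_t
        p_load = Xc.T @ t
        q_a = yc @ t
        v = p_load.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p_load)
        norm_v = np.linalg.norm(v)
        if norm_v < _EPS:
            break
        v /= norm_v
        s = s - v * (v @ s)
        R[:, a], q[a], V[:, a] = r, q_a, v
        a += 1
    if a == 0:
        return np.zeros(p), x_mean, y_mean
    coef = R[:, :a] @ q[:a]
    return coef, x_mean, y_mean


def pls_fit_predict(X_train, y_train, X_test, n_components: int) -> np.ndarray:
    coef, x_mean, y_mean = pls_coefficients(X_train, y_train, n_components)
    return (np.asarray(X_test, dtype=float) - x_mean) @ coef + y_mean


def make_folds(n: int, k: int, rng: np.random.Generator):
    """Seeded k-fold partition: shuffled indices cut into k near-equal blocks."""
    if k < 2 or k > n:
        raise ValueError(f"need 2 <= cv_folds <= n_samples, got k={k}, n={n}")
    perm = rng.permutation(n)
    blocks = np.array_split(perm, k)
    return [(np.setdiff1d(perm, b, assume_unique=True), b) for b in blocks]


def cv_rmse(X: np.ndarray, y: np.ndarray, folds, max_factors: int) -> float:
    """Pooled RMSE of k-fold cross-validated PLS predictions (RMSECV).

    An empty design (zero columns) cannot predict and scores +inf.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if X.shape[1] == 0:
        return np.inf
    sq_sum = 0.0
    n_total = 0
    for train_idx, test_idx in folds:
        ncomp = min(max_factors, X.shape[1], len(train_idx) - 1)
        pred = pls_fit_predict(X[train_idx], y[train_idx], X[test_idx], ncomp)
        sq_sum += float(np.sum((y[test_idx] - pred) ** 2))
        n_total += len(test_idx)
    return np.sqrt(sq_sum / n_total)
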