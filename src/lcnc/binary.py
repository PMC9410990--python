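"""The two binary classification cores: PLSDA and LS-SVM.

PLSDA regresses a ±1 class code on the feature matrix by deflation-based
PLS1, truncated to a small number of latent variables; a sample is
assigned by the sign of its predicted response relative to a decision
threshold.  With *balanced centering* on (the default for one-vs-rest
submodels, where class sizes are severely unequal) the threshold sits
midway between the two class-mean fitted responses instead of at the
response origin, so the majority class does not bias the boundary.

LS-SVM is the least-squares variant of the support vector machine with
an RBF kernel: equality constraints and squared-error loss reduce
training to one (n+1)x(n+1) linear system

    [[0, 1'], [1, K + I/gamma]] [b; alpha] = [0; y]

with kernel K[i,j] = exp(-||x_i - x_j||^2 / sigma^2).  The response of a
new point is sum_i alpha_i K(x_i, x) + b, thresholded at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PLSDAModel", "LSSVMModel",
    "fit_plsda", "predict_plsda",
    "rbf_kernel", "fit_lssvm", "predict_lssvm",
]


@dataclass
class PLSDAModel:
    n_lv: int
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: float
    weights: np.ndarray        # p x n_lv
    loadings: np.ndarray       # p x n_lv
    y_loadings: np.ndarray     # n_lv
    regression_vector: np.ndarray  # p, on the original feature scale
    intercept: float
    decision_threshold: float
    class_weighting: bool


def fit_plsda(X, y, n_lv: int, class_weighting: bool = False) -> PLSDAModel:
    """Fit a PLS1 discriminant model of the ±1 code ``y`` on ``X``.

    Features are auto-scaled internally from the training data.  The
    deflation loop is the classical PLS1: weight w ∝ X'y, score t = Xw,
    loadings p = X't/t't, q = y't/t't, then rank-one deflation of X and
    y.  ``n_lv`` may not exceed min(n-1, p) nor the rank actually met
    during deflation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    classes = np.unique(y)
    if not np.array_equal(classes, [-1.0, 1.0]):
        raise ValueError("y must contain both +1 and -1")
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    if n_lv > min(n - 1, p):
        raise ValueError(f"n_lv={n_lv} exceeds min(n-1, p)={min(n - 1, p)}")

    x_center = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=1)
    x_scale[x_scale == 0] = 1.0
    Xc = (X - x_center) / x_scale
    y_center = float(y.mean())
    yc = y - y_center

    Xd, yd = Xc.copy(), yc.copy()
    W = np.empty((p, n_lv))
    P = np.empty((p, n_lv))
    q = np.empty(n_lv)
    for a in range(n_lv):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < 1e-12 * max(1.0, np.linalg.norm(Xc)):
            raise ValueError(f"n_lv={n_lv} exceeds the effective rank ({a})")
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-24:
            raise ValueError(f"n_lv={n_lv} exceeds the effective rank ({a})")
        pl = Xd.T @ t / tt
        ql = float(yd @ t / tt)
        Xd -= np.outer(t, pl)
        yd -= ql * t
        W[:, a], P[:, a], q[a] = w, pl, ql

    # b on the scaled features, then fold the scaling in
    b_scaled = W @ np.linalg.solve(P.T @ W, q)
    b = b_scaled / x_scale
    intercept = y_center - float(x_center @ b)

    responses = X @ b + intercept
    if class_weighting:
        thr = 0.5 * (responses[y > 0].mean() + responses[y < 0].mean())
    else:
        thr = 0.0
    return PLSDAModel(
        n_lv=n_lv, x_center=x_center, x_scale=x_scale, y_center=y_center,
        weights=W, loadings=P, y_loadings=q, regression_vector=b,
        intercept=intercept, decision_threshold=float(thr),
        class_weighting=class_weighting,
    )


def predict_plsda(model: PLSDAModel, X):
    """Continuous responses and ±1 signs relative to the threshold."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.regression_vector.shape[0]:
        raise ValueError(
            f"matrix has {X.shape[1]} columns, model expects "
            f"{model.regression_vector.shape[0]}")
    responses = X @ model.regression_vector + model.intercept
    signs = np.where(responses >= model.decision_threshold, 1.0, -1.0)
    return responses, signs


def rbf_kernel(X, Z, sigma: float) -> np.ndarray:
    """K[i, j] = exp(-||x_i - z_j||^2 / sigma^2)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    sq = (
        (X ** 2).sum(axis=1)[:, None]
        + (Z ** 2).sum(axis=1)[None, :]
        - 2.0 * X @ Z.T
    )
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-sq / sigma ** 2)


@dataclass
class LSSVMModel:
    alphas: np.ndarray
    bias: float
    sigma: float
    gamma: float
    support_X: np.ndarray
    kkt_residual: float


def fit_lssvm(X, y, sigma: float, gamma: float) -> LSSVMModel:
    """Solve the LS-SVM dual system for ``(alphas, bias)``.

    The (n+1)-dimensional system is solved directly; its relative
    residual is stored and must be tiny (the system is positive definite
    off the border row for any finite gamma > 0).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if sigma <= 0 or gamma <= 0:
        raise ValueError("sigma and gamma must be > 0")
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    n = X.shape[0]
    K = rbf_kernel(X, X, sigma)
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / gamma
    rhs = np.concatenate(([0.0], y))
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"LS-SVM system is singular: {e}") from None
    resid = np.linalg.norm(A @ sol - rhs) / np.linalg.norm(rhs)
    return LSSVMModel(alphas=sol[1:], bias=float(sol[0]), sigma=sigma,
                      gamma=gamma, support_X=X, kkt_residual=float(resid))


def predict_lssvm(model: LSSVMModel, X):
    """Responses sum_i alpha_i K(x_i, x) + b and their signs."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.support_X.shape[1]:
        raise ValueError(
            f"matrix has {X.shape[1]} columns, model expects "
            f"{model.support_X.shape[1]}")
    K = rbf_kernel(X, model.support_X, model.sigma)
    responses = K @ model.alphas + model.bias
    signs = np.where(responses >= 0, 1.0, -1.0)
    return responses, signs
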