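"""Hyperparameter selection and cross-validation.

PLSDA complexity (number of latent variables) is chosen by Monte Carlo
cross-validation: the calibration set is split at random into 80%
training / 20% validation many times, and the pooled misclassification
rate

    MR_MCCV = (sum_i m_i) / (sum_i v_i)

over the splits (m_i misclassified of v_i validation objects in split i)
is minimized over the candidate LV counts.  Note the ratio-of-sums form:
splits with more validation objects weigh more than in a mean of
per-split rates.

LS-SVM hyperparameters (sigma, gamma) are chosen on a log-spaced grid by
stratified 10-fold cross-validation minimizing RMSECV, the root mean
squared error between the ±1 codes and the continuous responses of
held-out samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binary import fit_lssvm, fit_plsda, predict_lssvm, predict_plsda

__all__ = [
    "BinarySpec", "MCCVResult", "GridSearchResult",
    "mccv_mr", "select_plsda_lv", "grid_search_lssvm",
    "default_sigma_grid", "default_gamma_grid",
    "fit_binary", "predict_binary", "cross_validate_system",
]

_MAX_REDRAWS = 50


def default_sigma_grid(p: int) -> np.ndarray:
    """2^-3 .. 2^7 times sqrt(p): kernel widths spanning sub-feature to
    whole-cloud scales on auto-scaled data."""
    return np.sqrt(p) * 2.0 ** np.arange(-3, 8)


def default_gamma_grid() -> np.ndarray:
    """2^-5 .. 2^10: strong regularization to near-interpolation."""
    return 2.0 ** np.arange(-5, 11)


@dataclass
class BinarySpec:
    """Configuration of a binary submodel and its selection procedure.

    ``class_weighting=None`` leaves the choice to the multiclass
    strategy: balanced centering on for one-vs-rest submodels (unequal
    class sizes), off for pairwise submodels.
    """

    classifier: str = "plsda"          # "plsda" | "lssvm"
    class_weighting: bool | None = None
    max_lv: int = 10
    n_splits: int = 100
    val_frac: float = 0.2
    sigma_grid: tuple | None = None    # None -> default_sigma_grid(p)
    gamma_grid: tuple | None = None    # None -> default_gamma_grid()
    folds: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.classifier not in ("plsda", "lssvm"):
            raise ValueError(f"unknown classifier {self.classifier!r}")


@dataclass
class MCCVResult:
    mr_per_lv: np.ndarray
    chosen_lv: int
    n_splits: int
    val_frac: float
    seed: int


@dataclass
class GridSearchResult:
    sigma_grid: np.ndarray
    gamma_grid: np.ndarray
    rmsecv: np.ndarray          # len(sigma_grid) x len(gamma_grid)
    chosen_sigma: float
    chosen_gamma: float
    folds: int
    seed: int


def mccv_mr(m, v) -> float:
    """Pooled misclassification rate: ratio of summed miscounts to summed
    validation sizes (not the mean of per-split rates)."""
    m = np.asarray(m, dtype=float)
    v = np.asarray(v, dtype=float)
    if m.shape != v.shape:
        raise ValueError("m and v must have equal length")
    if np.any(m < 0) or np.any(m > v):
        raise ValueError("need 0 <= m_i <= v_i")
    tot = v.sum()
    if tot == 0:
        raise ValueError("no validation objects")
    return float(m.sum() / tot)


def _random_split(rng, y, n_val):
    """One calibration/validation partition whose calibration part holds
    both classes; redraws bounded."""
    n = len(y)
    for _ in range(_MAX_REDRAWS):
        perm = rng.permutation(n)
        val, cal = perm[:n_val], perm[n_val:]
        if len(np.unique(y[cal])) == 2:
            return cal, val
    raise ValueError("could not draw a calibration set with both classes")


def select_plsda_lv(X, y, max_lv: int = 10, n_splits: int = 100,
                    val_frac: float = 0.2, seed: int = 0,
                    class_weighting: bool = False) -> MCCVResult:
    """Choose the PLSDA latent-variable count by MCCV.

    For each split, models with 1..max_lv latent variables are fitted on
    the calibration part and their sign errors counted on the validation
    part; the LV count minimizing the pooled misclassification rate is
    chosen (ties to the smallest LV).  ``max_lv`` is capped by the
    dimensions of the calibration part.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    rng = np.random.default_rng(seed)
    n_val = max(1, int(round(val_frac * n)))
    if n - n_val < 2:
        raise ValueError("calibration part too small")
    lv_cap = min(max_lv, n - n_val - 1, p)
    m = np.zeros((lv_cap, n_splits))
    v = np.zeros(n_splits)
    for s in range(n_splits):
        cal, val = _random_split(rng, y, n_val)
        v[s] = len(val)
        for lv in range(1, lv_cap + 1):
            try:
                model = fit_plsda(X[cal], y[cal], lv,
                                  class_weighting=class_weighting)
            except ValueError:
                # beyond the rank of this calibration draw: count as all wrong
                m[lv - 1, s] = len(val)
                continue
            _, signs = predict_plsda(model, X[val])
            m[lv - 1, s] = np.sum(signs != y[val])
    mr = np.array([mccv_mr(m[i], v) for i in range(lv_cap)])
    chosen = int(np.argmin(mr)) + 1   # argmin takes the first = smallest LV
    return MCCVResult(mr_per_lv=mr, chosen_lv=chosen, n_splits=n_splits,
                      val_frac=val_frac, seed=seed)


def _stratified_folds(rng, y, folds):
    """Fold labels dealt round-robin within each class after shuffling."""
    n = len(y)
    assign = np.empty(n, dtype=int)
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        idx = rng.permutation(idx)
        assign[idx] = np.arange(len(idx)) % folds
    return assign


def grid_search_lssvm(X, y, sigma_grid=None, gamma_grid=None,
                      folds: int = 10, seed: int = 0) -> GridSearchResult:
    """Grid search of (sigma, gamma) minimizing RMSECV.

    Folds are stratified by class and seeded; every grid point is scored
    on the same folds.  Ties go to the smaller sigma, then the smaller
    gamma, independent of grid ordering.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    sigma_grid = (default_sigma_grid(p) if sigma_grid is None
                  else np.asarray(sigma_grid, dtype=float))
    gamma_grid = (default_gamma_grid() if gamma_grid is None
                  else np.asarray(gamma_grid, dtype=float))
    if sigma_grid.size == 0 or gamma_grid.size == 0:
        raise ValueError("grids must be nonempty")
    folds = min(folds, n)
    rng = np.random.default_rng(seed)
    for _ in range(_MAX_REDRAWS):
        assign = _stratified_folds(rng, y, folds)
        if all(len(np.unique(y[assign != f])) == 2 for f in range(folds)):
            break
    else:
        raise ValueError("could not stratify folds with both classes")

    sq_err = np.zeros((len(sigma_grid), len(gamma_grid)))
    for f in range(folds):
        tr, te = assign != f, assign == f
        if not te.any():
            continue
        for i, sg in enumerate(sigma_grid):
            for j, gm in enumerate(gamma_grid):
                model = fit_lssvm(X[tr], y[tr], sg, gm)
                resp, _ = predict_lssvm(model, X[te])
                sq_err[i, j] += np.sum((y[te] - resp) ** 2)
    rmsecv = np.sqrt(sq_err / n)
    # tie-break by value: smallest RMSECV, then smallest sigma, then gamma
    best = None
    for i in np.argsort(sigma_grid, kind="stable"):
        for j in np.argsort(gamma_grid, kind="stable"):
            if best is None or rmsecv[i, j] < best[0]:
                best = (rmsecv[i, j], i, j)
    _, bi, bj = best
    return GridSearchResult(sigma_grid=sigma_grid, gamma_grid=gamma_grid,
                            rmsecv=rmsecv,
                            chosen_sigma=float(sigma_grid[bi]),
                            chosen_gamma=float(gamma_grid[bj]),
                            folds=folds, seed=seed)


def fit_binary(X, y, spec: BinarySpec, balanced: bool, seed: int):
    """Select hyperparameters on (X, y) and fit the final binary model.

    ``balanced`` is the strategy's default for class weighting, used when
    the spec leaves it unset.  Returns (model, selection_result).
    """
    weighting = (balanced if spec.class_weighting is None
                 else spec.class_weighting)
    if spec.classifier == "plsda":
        n = len(y)
        max_lv = min(spec.max_lv,
                     max(1, n - max(1, int(round(spec.val_frac * n))) - 1),
                     np.asarray(X).shape[1])
        sel = select_plsda_lv(X, y, max_lv=max_lv, n_splits=spec.n_splits,
                              val_frac=spec.val_frac, seed=seed,
                              class_weighting=weighting)
        model = fit_plsda(X, y, sel.chosen_lv, class_weighting=weighting)
    else:
        sel = grid_search_lssvm(X, y, sigma_grid=spec.sigma_grid,
                                gamma_grid=spec.gamma_grid,
                                folds=spec.folds, seed=seed)
        model = fit_lssvm(X, y, sel.chosen_sigma, sel.chosen_gamma)
    return model, sel


def predict_binary(model, X):
    """Dispatch continuous responses and signs for either binary core."""
    from .binary import LSSVMModel, PLSDAModel
    if isinstance(model, PLSDAModel):
        resp, signs = predict_plsda(model, X)
        return resp - model.decision_threshold, signs
    if isinstance(model, LSSVMModel):
        return predict_lssvm(model, X)
    raise TypeError(f"unknown binary model type {type(model)!r}")


def cross_validate_system(train, strategy: str, spec: BinarySpec,
                          folds: int = 10, seed: int = 0) -> float:
    """Stratified k-fold accuracy of a full multiclass system.

    The whole pipeline — hyperparameter selection included — is refit on
    every fold's training part, so held-out objects never influence the
    selected LV counts or (sigma, gamma).
    """
    from .multiclass import fit_system, predict_table

    if train.labels is None:
        raise ValueError("training table has no labels")
    y = train.labels
    rng = np.random.default_rng(seed)
    assign = _stratified_folds(rng, y, folds)
    for c in np.unique(y):
        for f in range(folds):
            if np.sum((y == c) & (assign != f)) < 2:
                raise ValueError(
                    f"class {c!r} has fewer than 2 training samples "
                    f"in fold {f}")
    correct = 0
    for f in range(folds):
        tr = train.take_rows(np.flatnonzero(assign != f))
        te = train.take_rows(np.flatnonzero(assign == f))
        if te.n_samples == 0:
            continue
        system = fit_system(tr, strategy, spec)
        pred = predict_table(system, te)
        correct += int(np.sum(pred == te.labels))
    return correct / train.n_samples
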