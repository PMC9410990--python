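"""Auto-scaling, robust outlier diagnosis and representative splitting.

Three preparation stages precede classification:

* **auto-scaling** — every feature centred to zero mean and scaled to
  unit standard deviation (n-1 denominator), so concentrations spanning
  four orders of magnitude do not dominate the isotope ratios;
* **Stahel–Donoho outlyingness** — a robust score per sample: the worst
  standardized deviation from the bulk over many random projection
  directions, location/scale taken as median and MAD.  Scores above 3
  (a 3-sigma rule; the MAD carries the 1.4826 consistency factor) flag
  outliers.  Diagnosis is run within each class separately;
* **DUPLEX splitting** — a deterministic farthest-point algorithm that
  divides each class into training and test subsets that both span the
  occupied region of feature space, run per class and concatenated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import FeatureTable

__all__ = [
    "ScalingParams", "OutlierReport", "SplitPlan",
    "autoscale_fit", "autoscale_apply",
    "sde_outlyingness", "detect_outliers_by_class",
    "duplex_split", "split_dataset", "equal_quotas",
]

MAD_CONSISTENCY = 1.4826  # makes MAD estimate sigma at the Gaussian


@dataclass
class ScalingParams:
    center: np.ndarray
    scale: np.ndarray


def autoscale_fit(X, feature_names=None) -> ScalingParams:
    """Column means and standard deviations (n-1 denominator).

    Raises if any column has zero variance, naming the offending feature.
    """
    X = np.asarray(X, dtype=float)
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(scale == 0)
    if bad.size:
        names = ([feature_names[j] for j in bad] if feature_names is not None
                 else [f"column {j}" for j in bad])
        raise ValueError(f"zero-variance feature(s): {names}")
    return ScalingParams(center=center, scale=scale)


def autoscale_apply(X, params: ScalingParams) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.center.shape[0]:
        raise ValueError(
            f"matrix has {X.shape[1]} columns, scaling expects "
            f"{params.center.shape[0]}")
    return (X - params.center) / params.scale


@dataclass
class OutlierReport:
    """Per-sample Stahel–Donoho scores with the cutoff applied."""

    scores: np.ndarray
    cutoff: float
    flags: np.ndarray
    n_projections: int
    seed: int


def sde_outlyingness(X, n_projections: int = 500, seed: int = 0,
                     cutoff: float = 3.0) -> OutlierReport:
    """Stahel–Donoho outlyingness by random projections.

    For each of ``n_projections`` directions a, drawn uniformly on the
    unit sphere, every sample's projected value is standardized by the
    median and 1.4826*MAD of the projected cloud; a sample's score is its
    maximum absolute standardized value over directions.  Directions on
    which the projected MAD is zero are degenerate and skipped.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    if n_projections < 1:
        raise ValueError("n_projections must be >= 1")
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n_projections, p))
    A /= np.linalg.norm(A, axis=1, keepdims=True)
    proj = X @ A.T                                  # n x n_projections
    med = np.median(proj, axis=0)
    mad = np.median(np.abs(proj - med), axis=0)
    ok = mad > 0
    if not ok.any():
        raise ValueError("all projection directions degenerate (MAD = 0)")
    z = np.abs(proj[:, ok] - med[ok]) / (MAD_CONSISTENCY * mad[ok])
    scores = z.max(axis=1)
    return OutlierReport(scores=scores, cutoff=cutoff,
                         flags=scores > cutoff,
                         n_projections=n_projections, seed=seed)


def detect_outliers_by_class(table: FeatureTable, n_projections: int = 500,
                             seed: int = 0, cutoff: float = 3.0
                             ) -> OutlierReport:
    """Per-class Stahel–Donoho diagnosis on auto-scaled features.

    Features are auto-scaled over the whole table, then each class's
    rows are scored independently; the per-class scores are assembled
    back into one report aligned with the table's rows.
    """
    params = autoscale_fit(table.values, table.feature_names)
    Xs = autoscale_apply(table.values, params)
    scores = np.empty(table.n_samples)
    for i, c in enumerate(table.classes()):
        idx = table.rows_for_class(c)
        rep = sde_outlyingness(Xs[idx], n_projections=n_projections,
                               seed=seed + i, cutoff=cutoff)
        scores[idx] = rep.scores
    return OutlierReport(scores=scores, cutoff=cutoff, flags=scores > cutoff,
                         n_projections=n_projections, seed=seed)


@dataclass
class SplitPlan:
    """Index assignment of one class's samples to train and test."""

    train_indices: list
    test_indices: list


def _farthest_from_set(D: np.ndarray, chosen: list, remaining: set) -> int:
    """Max-min criterion: the remaining point whose minimum distance to the
    chosen set is largest; ties go to the lowest row index."""
    rem = sorted(remaining)
    dmin = D[np.ix_(rem, chosen)].min(axis=1)
    return rem[int(np.argmax(dmin))]


def duplex_split(X_class, n_train: int, n_test: int) -> SplitPlan:
    """Deterministic DUPLEX assignment of one class's samples.

    The two mutually farthest points (Euclidean) seed the training set
    and the farthest remaining pair seeds the test set; thereafter the
    point farthest (max-min distance) from each growing set is added
    alternately until the test quota is reached, when every remaining
    point joins the training set.  Unequal quotas such as 20/10 are
    honoured exactly.
    """
    X = np.asarray(X_class, dtype=float)
    n = X.shape[0]
    if n_train + n_test != n:
        raise ValueError(f"quotas {n_train}+{n_test} != {n} samples")
    if n_train < 2 or n_test < 2:
        raise ValueError("both subsets need at least 2 samples")
    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt((diff ** 2).sum(axis=2))

    def farthest_pair(idx):
        idx = sorted(idx)
        sub = D[np.ix_(idx, idx)]
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        a, b = idx[i], idx[j]
        return (a, b) if a < b else (b, a)

    remaining = set(range(n))
    train = list(farthest_pair(remaining))
    remaining -= set(train)
    test = list(farthest_pair(remaining))
    remaining -= set(test)

    turn_train = True
    while remaining:
        if len(test) == n_test:
            train.extend(sorted(remaining))
            break
        if len(train) == n_train:
            test.extend(sorted(remaining))
            break
        target, chosen = ((train, train) if turn_train else (test, test))
        nxt = _farthest_from_set(D, chosen, remaining)
        target.append(nxt)
        remaining.remove(nxt)
        turn_train = not turn_train
    return SplitPlan(train_indices=sorted(train), test_indices=sorted(test))


def equal_quotas(table: FeatureTable, n_train: int) -> dict:
    """Per-class (n_train, n_test) quotas with a fixed training count.

    Every class contributes ``n_train`` training samples and its
    remaining samples to the test set, so classes shortened by outlier
    removal lose test objects (e.g. 29 samples -> 20/9 instead of 20/10).
    """
    quotas = {}
    for c in table.classes():
        n = len(table.rows_for_class(c))
        if n - n_train < 2:
            raise ValueError(
                f"class {c!r}: {n} samples leave fewer than 2 for testing")
        quotas[c] = (n_train, n - n_train)
    return quotas


def split_dataset(table: FeatureTable, quotas: dict):
    """Per-class DUPLEX splits concatenated into train and test tables.

    ``quotas`` maps class label -> (n_train, n_test).  Each class's rows
    are split independently on the table's (unscaled) features, so the
    result is invariant to the interleaving of classes in the input.
    """
    if table.labels is None:
        raise ValueError("table has no labels")
    train_rows, test_rows = [], []
    for c in table.classes():
        if c not in quotas:
            raise ValueError(f"no quota for class {c!r}")
        idx = table.rows_for_class(c)
        n_train, n_test = quotas[c]
        plan = duplex_split(table.values[idx], n_train, n_test)
        train_rows.extend(idx[plan.train_indices])
        test_rows.extend(idx[plan.test_indices])
    return table.take_rows(train_rows), table.take_rows(test_rows)
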