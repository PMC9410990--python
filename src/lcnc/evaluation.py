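"""Accuracy reporting and exploratory analyses (PCA, HCA).

Classification quality is summarized by a confusion matrix (rows: true
class, columns: predicted) and its total accuracy (trace over total).
Exploration mirrors common chemometrics practice: PCA of the auto-scaled
table via singular value decomposition, and hierarchical clustering of
the per-class average fingerprints with Euclidean distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import pdist

from .data_io import FeatureTable
from .preprocessing import autoscale_apply, autoscale_fit

__all__ = [
    "ConfusionMatrix", "PCAResult", "LinkageTree",
    "confusion_matrix", "accuracy", "pca", "hca_class_averages",
]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray
    classes: list


def confusion_matrix(y_true, y_pred, classes=None) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if classes is None:
        classes = list(dict.fromkeys(list(y_true) + list(y_pred)))
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=list(classes))


def accuracy(cm: ConfusionMatrix) -> float:
    """Total classification accuracy: trace / total count."""
    total = cm.counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / total)


@dataclass
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray                    # p x n_components
    explained_variance_fractions: np.ndarray


def pca(X_scaled, n_components: int) -> PCAResult:
    """PCA of an already auto-scaled matrix by SVD.

    Variance fractions are singular values squared over their total, so
    on auto-scaled data they equal the correlation-matrix eigenvalue
    fractions.  Components are ordered by decreasing variance.
    """
    X = np.asarray(X_scaled, dtype=float)
    n, p = X.shape
    if n_components > min(n, p):
        raise ValueError(f"n_components={n_components} exceeds min(n, p)")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2
    frac = var / var.sum()
    return PCAResult(
        scores=U[:, :n_components] * s[:n_components],
        loadings=Vt[:n_components].T,
        explained_variance_fractions=frac[:n_components],
    )


@dataclass
class LinkageTree:
    """SciPy-format merge table: each of the n-1 rows is (cluster a,
    cluster b, merge height, merged size)."""

    merges: np.ndarray
    leaf_labels: list


def hca_class_averages(table: FeatureTable, method: str = "average"
                       ) -> LinkageTree:
    """Hierarchical clustering of per-class mean fingerprints.

    Features are auto-scaled over the whole table first; class averages
    are then merged agglomeratively on Euclidean distances with the
    given linkage (average by default).
    """
    classes = table.classes()
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    params = autoscale_fit(table.values, table.feature_names)
    Xs = autoscale_apply(table.values, params)
    means = np.vstack([Xs[table.rows_for_class(c)].mean(axis=0)
                       for c in classes])
    merges = _scipy_linkage(pdist(means), method=method)
    return LinkageTree(merges=merges, leaf_labels=classes)
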