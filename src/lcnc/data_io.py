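"""Feature tables and their CSV serialization.

The canonical in-memory container is :class:`FeatureTable`: an
``n_samples x n_features`` matrix of continuous measurements (element
concentrations in µg/g dry weight, stable-isotope ratios in ‰) with unique
sample ids, unique feature names and an optional per-sample class label
(the producing area).  Non-detected measurements are stored as NaN; a
feature that was never detected in any sample (an all-NaN column) can be
removed with :func:`drop_nondetected`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "ClassLabelMap",
    "read_feature_table",
    "write_feature_table",
    "drop_nondetected",
]

#: cell contents (after stripping, case-insensitive) treated as "non-detected"
MISSING_SENTINELS = {"", "nd"}


def _check_unique(names: Sequence, what: str) -> None:
    seen: dict = {}
    dups = []
    for x in names:
        if x in seen:
            dups.append(x)
        seen[x] = True
    if dups:
        raise ValueError(f"duplicate {what}: {sorted(set(map(str, dups)))}")


@dataclass
class FeatureTable:
    """A sample-by-feature table with ids, names and optional class labels.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_features)
        Measurements; NaN marks a non-detected value.
    sample_ids : list of str
        Unique identifier per row.
    feature_names : list of str
        Unique name per column.
    labels : ndarray or None
        Per-sample class identifier (opaque; strings or integers).
    """

    values: np.ndarray
    sample_ids: list = field(default_factory=list)
    feature_names: list = field(default_factory=list)
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        self.sample_ids = list(self.sample_ids)
        self.feature_names = list(self.feature_names)
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} rows"
            )
        if len(self.feature_names) != p:
            raise ValueError(
                f"{len(self.feature_names)} feature names for {p} columns"
            )
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.feature_names, "feature names")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise ValueError("labels must have one entry per sample")

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def classes(self) -> list:
        """Distinct labels in order of first appearance."""
        if self.labels is None:
            raise ValueError("table has no labels")
        return list(pd.unique(self.labels))

    def rows_for_class(self, label) -> np.ndarray:
        """Row indices of the samples carrying ``label``."""
        if self.labels is None:
            raise ValueError("table has no labels")
        return np.flatnonzero(self.labels == label)

    def take_rows(self, idx) -> "FeatureTable":
        idx = np.asarray(idx, dtype=int)
        return FeatureTable(
            self.values[idx],
            [self.sample_ids[i] for i in idx],
            list(self.feature_names),
            None if self.labels is None else self.labels[idx],
        )

    def take_features(self, names: Sequence[str]) -> "FeatureTable":
        pos = [self.feature_names.index(n) for n in names]
        return FeatureTable(
            self.values[:, pos], list(self.sample_ids), list(names),
            None if self.labels is None else self.labels.copy(),
        )

    def restrict_classes(self, subset) -> "FeatureTable":
        """Rows whose label is in ``subset`` (order of rows preserved)."""
        mask = np.isin(self.labels, list(subset))
        return self.take_rows(np.flatnonzero(mask))

    def to_dataframe(self, label_column: str | None = "class") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "id", self.sample_ids)
        if self.labels is not None and label_column:
            df[label_column] = self.labels
        return df


@dataclass
class ClassLabelMap:
    """Bijection between k class identifiers and 0-based positions."""

    classes: list

    def __post_init__(self):
        self.classes = list(self.classes)
        _check_unique(self.classes, "class identifiers")
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")
        self.index = {c: i for i, c in enumerate(self.classes)}

    @classmethod
    def from_labels(cls, labels) -> "ClassLabelMap":
        return cls(list(pd.unique(np.asarray(labels))))

    @property
    def k(self) -> int:
        return len(self.classes)

    def __contains__(self, c) -> bool:
        return c in self.index


def read_feature_table(
    path,
    label_column: str | None = None,
    id_column: str = "id",
) -> FeatureTable:
    """Read a delimiter-separated feature table with a header row.

    Empty cells and the sentinel ``ND`` (case-insensitive) are read as
    non-detected (NaN).  The column named ``id_column`` (if present)
    provides sample ids; otherwise ids ``s1..sn`` are generated.  Row
    order is preserved.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if id_column in cols:
        sample_ids = [str(x) for x in df[id_column]]
        cols.remove(id_column)
    else:
        sample_ids = [f"s{i + 1}" for i in range(len(df))]
    _check_unique(sample_ids, "sample ids")
    labels = None
    if label_column is not None:
        if label_column not in cols:
            raise ValueError(f"label column {label_column!r} not in file")
        labels = np.asarray(df[label_column])
        cols.remove(label_column)
    values = np.empty((len(df), len(cols)))
    for j, c in enumerate(cols):
        for i, cell in enumerate(df[c]):
            s = str(cell).strip()
            if s.lower() in MISSING_SENTINELS:
                values[i, j] = np.nan
            else:
                try:
                    values[i, j] = float(s)
                except ValueError:
                    raise ValueError(
                        f"non-numeric value {s!r} at row {i + 1}, column {c!r}"
                    ) from None
    return FeatureTable(values, sample_ids, cols, labels)


def write_feature_table(
    table: FeatureTable, path, label_column: str = "class"
) -> None:
    """Write a table as CSV; non-detected values become empty cells."""
    df = table.to_dataframe(label_column=label_column)
    df.to_csv(path, index=False, na_rep="")


def drop_nondetected(table: FeatureTable) -> FeatureTable:
    """Remove every feature whose column is entirely non-detected.

    Idempotent; preserves the order of the remaining features.  A feature
    with at least one detected value is kept.
    """
    keep = ~np.all(np.isnan(table.values), axis=0)
    if not keep.any():
        raise ValueError("all features are non-detected")
    return FeatureTable(
        table.values[:, keep],
        list(table.sample_ids),
        [n for n, k in zip(table.feature_names, keep) if k],
        None if table.labels is None else table.labels.copy(),
    )
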