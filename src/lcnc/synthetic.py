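"""Synthetic elemental/isotopic fingerprint datasets.

Real producing-area surveys of medicinal herbs are rarely deposited, so
the pipeline is exercised on synthetic tables that mirror the design of
the study this package models: 37 producing areas (classes) x 30 samples,
15 elements analysed by ICP-AES of which two (Se, Cd) fall below the
detection limit in every sample, plus three stable-isotope ratios —
16 usable features in all.  Per feature only the range and spread of the
37 class averages are known, so class means are drawn uniformly on the
published [lowest, highest] range of averages, independently across
features; within-class scatter is i.i.d. Gaussian with standard deviation
``within_class_sd_fraction`` times the published between-class sd of
averages.  Gross outliers are planted by displacing single samples along
a random direction by a stated multiple of the within-class sd, emulating
the three outlying objects the study removed (one each in classes 20, 27
and 37).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import FeatureTable

__all__ = ["FeatureSpec", "OutlierPlan", "SyntheticSpec", "small_spec",
           "default_spec", "generate_dataset"]

#: (name, lowest of class averages, highest, sd of class averages).
#: Element concentrations in µg/g dry weight, isotope ratios in the delta
#: units of the source survey.  Se and Cd carry no statistics: they were
#: below the detection limit everywhere.
_FEATURE_SUMMARY = [
    ("Se", None, None, None),
    ("Cd", None, None, None),
    ("Fe", 45.0, 809.0, 211.0),
    ("Na", 319.0, 4615.0, 1123.0),
    ("Sr", 0.912, 8.228, 1.9),
    ("Co", 0.587, 4.729, 1.1),
    ("K", 3050.0, 11330.0, 2091.0),
    ("Al", 33.0, 415.0, 116.0),
    ("Cr", 0.315, 20.8, 5.5),
    ("Mg", 1639.0, 4578.0, 819.0),
    ("Pb", 0.039, 0.408, 0.09),
    ("Zn", 2.965, 22.80, 5.1),
    ("Ca", 857.0, 6623.0, 1270.0),
    ("Cu", 3.25, 10.77, 2.1),
    ("Mn", 8.56, 30.75, 6.7),
    ("d13C", -34.1, -27.1, 1.8),
    ("d15N", -4.97, -2.15, 0.8),
    ("d18O", 10.1, 15.3, 1.4),
]


@dataclass(frozen=True)
class FeatureSpec:
    """Between-class design of one feature.

    ``lowest_of_average``/``highest_of_average`` bound the k class means;
    ``sd_of_average`` is their spread and serves as the scale reference
    for within-class noise.  ``detected=False`` marks a feature reported
    below the detection limit in every sample (generated all-missing).
    """

    name: str
    lowest_of_average: float | None = None
    highest_of_average: float | None = None
    sd_of_average: float | None = None
    detected: bool = True

    def __post_init__(self):
        if self.detected:
            if None in (self.lowest_of_average, self.highest_of_average,
                        self.sd_of_average):
                raise ValueError(f"feature {self.name}: statistics required")
            if self.lowest_of_average > self.highest_of_average:
                raise ValueError(f"feature {self.name}: lowest > highest")
            if self.sd_of_average <= 0:
                raise ValueError(f"feature {self.name}: sd_of_average <= 0")


@dataclass(frozen=True)
class OutlierPlan:
    """One planted gross outlier: sample ``sample_index`` (0-based within
    class ``class_label``) is displaced by ``magnitude`` within-class
    standard deviations along a random direction."""

    class_label: int
    sample_index: int
    magnitude: float


@dataclass
class SyntheticSpec:
    """Full generative design of a synthetic survey."""

    k: int = 37
    n_per_class: int = 30
    feature_specs: list = field(default_factory=list)
    outlier_plan: list = field(default_factory=list)
    within_class_sd_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_per_class < 3:
            raise ValueError("n_per_class must be >= 3")
        if self.within_class_sd_fraction <= 0:
            raise ValueError("within_class_sd_fraction must be > 0")
        if not self.feature_specs:
            raise ValueError("no features specified")
        for o in self.outlier_plan:
            if not (1 <= o.class_label <= self.k):
                raise ValueError(f"outlier class {o.class_label} out of range")
            if not (0 <= o.sample_index < self.n_per_class):
                raise ValueError("outlier sample index out of range")

    @property
    def detected_features(self) -> list:
        return [f for f in self.feature_specs if f.detected]


def default_spec(seed: int = 0, within_class_sd_fraction: float = 0.25,
                 outlier_magnitude: float = 12.0) -> SyntheticSpec:
    """The study design: 37 classes x 30 samples, the published per-feature
    class-average ranges/spreads, Se and Cd fully non-detected, and one
    gross outlier planted in each of classes 20, 27 and 37."""
    feats = [
        FeatureSpec(name, lo, hi, sd, detected=lo is not None)
        for name, lo, hi, sd in _FEATURE_SUMMARY
    ]
    plan = [OutlierPlan(c, 0, outlier_magnitude) for c in (20, 27, 37)]
    return SyntheticSpec(
        k=37, n_per_class=30, feature_specs=feats, outlier_plan=plan,
        within_class_sd_fraction=within_class_sd_fraction, seed=seed,
    )


def generate_dataset(spec: SyntheticSpec, return_truth: bool = False):
    """Draw one dataset from ``spec``.

    Labels are the integers ``1..k``; sample ids are ``c<label>_<i>``.
    Identical seeds give identical tables.  With ``return_truth=True``
    also returns a dict with the drawn ``class_means`` (k x p_detected)
    and the global ``outlier_rows`` indices.
    """
    rng = np.random.default_rng(spec.seed)
    det = spec.detected_features
    p_det = len(det)
    k, n = spec.k, spec.n_per_class

    lows = np.array([f.lowest_of_average for f in det])
    highs = np.array([f.highest_of_average for f in det])
    sds = np.array([f.sd_of_average for f in det])
    within_sd = spec.within_class_sd_fraction * sds

    class_means = rng.uniform(lows, highs, size=(k, p_det))
    X = np.repeat(class_means, n, axis=0) \
        + rng.standard_normal((k * n, p_det)) * within_sd

    outlier_rows = []
    for o in spec.outlier_plan:
        row = (o.class_label - 1) * n + o.sample_index
        d = rng.standard_normal(p_det)
        d /= np.linalg.norm(d)
        X[row] += o.magnitude * d * within_sd
        outlier_rows.append(row)

    # assemble full matrix in spec feature order, NaN for non-detected
    names = [f.name for f in spec.feature_specs]
    full = np.full((k * n, len(names)), np.nan)
    det_pos = [j for j, f in enumerate(spec.feature_specs) if f.detected]
    full[:, det_pos] = X

    labels = np.repeat(np.arange(1, k + 1), n)
    ids = [f"c{c}_{i + 1}" for c in range(1, k + 1) for i in range(n)]
    table = FeatureTable(full, ids, names, labels)
    if return_truth:
        return table, {"class_means": class_means,
                       "outlier_rows": outlier_rows,
                       "within_sd": within_sd,
                       "detected_names": [f.name for f in det]}
    return table


def small_spec(k: int = 5, n_per_class: int = 12, n_features: int = 6,
               within_class_sd_fraction: float = 0.25,
               seed: int = 0) -> SyntheticSpec:
    """A reduced design using the first ``n_features`` detected features of
    the default spec — convenient for fast experiments and examples."""
    feats = [FeatureSpec(name, lo, hi, sd)
             for name, lo, hi, sd in _FEATURE_SUMMARY
             if lo is not None][:n_features]
    return SyntheticSpec(k=k, n_per_class=n_per_class, feature_specs=feats,
                         within_class_sd_fraction=within_class_sd_fraction,
                         seed=seed)
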