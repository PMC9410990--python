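"""Multiclass strategies for large class numbers.

Three ways of composing binary classifiers into a k-class decision:

* **OVR** (one-versus-rest): k binary models, class i coded +1 against
  the pooled remainder coded -1; a new object goes to the class with the
  highest continuous response.  Simple, but with many classes the
  severely unequal group sizes bias every boundary and a single bad
  response among k spoils the argmax.
* **OVO** (one-versus-one): k(k-1)/2 pairwise models, decision by
  max-wins voting.  Boundaries are estimated from balanced pairs, but
  votes from the many models not involving the true class accumulate
  noise.
* **ES** (ensemble strategy): a staged combination.  Stage 1 runs OVO
  over all k classes (subclassifier C1) and an OVR model over the 3
  classes with the most C1 votes (C2).  Each later stage i halves the
  candidate list — OVO over the alpha(i) = round(alpha(i-1)/2) classes
  ranked highest by C1's votes (C2i-1), then OVR over the top 3 of that
  OVO's votes (C2i) — stopping before a stage would drop below
  ``min_classes`` (default 10).  Every subclassifier contributes one
  vote (its winner); the final class is chosen by max-wins over those
  votes, and an exact tie is resolved by a dedicated OVR model over the
  tied classes.  For k=37 the schedule is 37 -> 19 -> 10: three stages,
  six subclassifiers.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .data_io import ClassLabelMap, FeatureTable
from .model_selection import BinarySpec, fit_binary, predict_binary
from .preprocessing import ScalingParams, autoscale_apply, autoscale_fit

__all__ = [
    "PairwisePool", "OVRModel", "ESSchedule", "ESModel", "Prediction",
    "MulticlassSystem",
    "fit_pairwise_pool", "ovo_predict", "fit_ovr", "ovr_predict",
    "es_schedule", "fit_es", "es_predict", "vote_rank", "max_wins",
    "fit_system", "predict_table",
]


def _subseed(base: int, *tags: int) -> int:
    """Deterministic per-submodel seed derived from the spec seed."""
    ss = np.random.SeedSequence([int(base) & 0x7FFFFFFF,
                                 *(int(t) & 0x7FFFFFFF for t in tags)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------- OVO --

@dataclass
class PairwisePool:
    """One binary model per unordered class pair.

    ``models`` maps frozenset({a, b}) -> (model, positive_class,
    negative_class); the positive class is the pair member appearing
    earlier in ``classes``.
    """

    classes: list
    models: dict
    spec: BinarySpec

    def model_for(self, a, b):
        return self.models[frozenset((a, b))]


@dataclass
class OvoResult:
    votes: dict
    response_sums: dict
    winner: object


def fit_pairwise_pool(train: FeatureTable, spec: BinarySpec) -> PairwisePool:
    """Fit all k(k-1)/2 pairwise models, each on its two classes' samples
    only, with hyperparameters selected per pair."""
    cmap = ClassLabelMap.from_labels(train.labels)
    for c in cmap.classes:
        if len(train.rows_for_class(c)) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 training samples")
    models = {}
    for i, ci in enumerate(cmap.classes):
        for j in range(i + 1, cmap.k):
            cj = cmap.classes[j]
            idx = np.concatenate([train.rows_for_class(ci),
                                  train.rows_for_class(cj)])
            X = train.values[idx]
            y = np.where(train.labels[idx] == ci, 1.0, -1.0)
            model, _ = fit_binary(X, y, spec, balanced=False,
                                  seed=_subseed(spec.seed, i, j))
            models[frozenset((ci, cj))] = (model, ci, cj)
    return PairwisePool(classes=cmap.classes, models=models, spec=spec)


def ovo_predict(pool: PairwisePool, x, class_subset=None) -> OvoResult:
    """Max-wins vote of the pairwise models within ``class_subset``.

    Each pair model contributes one vote and a signed continuous margin
    credited to the class it favours; the winner is the class with the
    most votes, ties resolved toward the earliest class in the pool's
    class order (the ensemble strategy applies its own tie rule on top).
    """
    subset = pool.classes if class_subset is None else list(class_subset)
    if len(subset) < 2:
        raise ValueError("need at least 2 classes to vote on")
    known = set(pool.classes)
    for c in subset:
        if c not in known:
            raise ValueError(f"class {c!r} unknown to the pool")
    votes = {c: 0 for c in subset}
    sums = {c: 0.0 for c in subset}
    for i, ci in enumerate(subset):
        for cj in subset[i + 1:]:
            model, pos, neg = pool.model_for(ci, cj)
            resp, _ = predict_binary(model, np.atleast_2d(x))
            margin = float(resp[0])
            winner_c = pos if margin >= 0 else neg
            votes[winner_c] += 1
            sums[pos] += margin
            sums[neg] -= margin
    order = {c: k for k, c in enumerate(pool.classes)}
    winner = max(subset, key=lambda c: (votes[c], -order[c]))
    return OvoResult(votes=votes, response_sums=sums, winner=winner)


def vote_rank(votes: dict, top_m: int, response_sums: dict | None = None,
              class_order=None) -> list:
    """Classes by descending vote count; ties by descending continuous
    response sum, then by class order.  Returns the first ``top_m``."""
    classes = list(votes)
    if top_m > len(classes):
        raise ValueError("top_m exceeds the number of classes voted on")
    order = {c: i for i, c in enumerate(
        classes if class_order is None else class_order)}
    sums = response_sums or {}
    ranked = sorted(classes,
                    key=lambda c: (-votes[c], -sums.get(c, 0.0), order[c]))
    return ranked[:top_m]


def max_wins(winners) -> list:
    """Classes receiving the maximal number of votes, in first-vote order.

    A single element means an outright winner; several mean a tie that
    the caller must break."""
    winners = list(winners)
    counts = Counter(winners)
    best = max(counts.values())
    return [c for c in dict.fromkeys(winners) if counts[c] == best]


# ---------------------------------------------------------------- OVR --

@dataclass
class OVRModel:
    """One class-vs-rest binary model per class of a stated subset, each
    trained only on the subset's samples with balanced centering on."""

    classes: list
    models: dict
    spec: BinarySpec


def fit_ovr(train: FeatureTable, class_subset, spec: BinarySpec) -> OVRModel:
    subset = list(class_subset)
    if len(subset) < 2:
        raise ValueError("need at least 2 classes")
    sub = train.restrict_classes(subset)
    present = set(np.unique(sub.labels)) if sub.n_samples else set()
    for c in subset:
        if c not in present:
            raise ValueError(f"class {c!r} has no training samples")
    models = {}
    for m, c in enumerate(subset):
        y = np.where(sub.labels == c, 1.0, -1.0)
        model, _ = fit_binary(sub.values, y, spec, balanced=True,
                              seed=_subseed(spec.seed, 7919, m))
        models[c] = model
    return OVRModel(classes=subset, models=models, spec=spec)


def ovr_predict(model: OVRModel, x):
    """Continuous response per class (threshold-centred) and the argmax
    winner; ties toward the earlier class in the subset order."""
    responses = {}
    for c in model.classes:
        resp, _ = predict_binary(model.models[c], np.atleast_2d(x))
        responses[c] = float(resp[0])
    order = {c: i for i, c in enumerate(model.classes)}
    winner = max(model.classes, key=lambda c: (responses[c], -order[c]))
    return responses, winner


# ----------------------------------------------------------------- ES --

@dataclass
class ESSchedule:
    """Stage class-counts [k, round(k/2), ...] down to ``min_classes``."""

    stage_counts: list
    min_classes: int = 10

    @property
    def n_stages(self) -> int:
        return len(self.stage_counts)

    @property
    def n_subclassifiers(self) -> int:
        return 2 * len(self.stage_counts)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def es_schedule(k: int, min_classes: int = 10,
                mode: str = "recursive") -> ESSchedule:
    """Class-halving schedule of the ensemble strategy.

    ``mode="recursive"`` halves the previous stage count with round-half-
    up (37 -> 19 -> 10), stopping before a stage would fall below
    ``min_classes``.  ``mode="formula"`` evaluates round(k / 2^(i-1))
    directly (37 -> 19 -> 9-stop), kept for comparison.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = [k]
    i = 1
    while True:
        if mode == "recursive":
            nxt = _round_half_up(counts[-1] / 2)
        elif mode == "formula":
            nxt = _round_half_up(k / 2 ** i)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if nxt < min_classes or nxt < 2 or nxt >= counts[-1]:
            break
        counts.append(nxt)
        i += 1
    return ESSchedule(stage_counts=counts, min_classes=min_classes)


@dataclass
class Prediction:
    predicted_class: object
    votes: dict                   # subclassifier id ("C1"...) -> voted class
    tie_broken: bool


@dataclass
class ESModel:
    """Fitted ensemble strategy: the full pairwise pool, the schedule,
    the training table for on-demand OVR submodels, and a cache of OVR
    models keyed by class subset (reused across test objects)."""

    pool: PairwisePool
    schedule: ESSchedule
    train: FeatureTable
    spec: BinarySpec
    ovr_cache: dict = field(default_factory=dict)

    def ovr_for(self, subset) -> OVRModel:
        key = frozenset(subset)
        if key not in self.ovr_cache:
            self.ovr_cache[key] = fit_ovr(self.train, sorted(
                subset, key={c: i for i, c in
                             enumerate(self.pool.classes)}.get), self.spec)
        return self.ovr_cache[key]


def fit_es(train: FeatureTable, spec: BinarySpec,
           min_classes: int = 10, mode: str = "recursive") -> ESModel:
    """Train the pairwise pool up front and compute the stage schedule;
    OVR submodels are trained on demand during prediction and cached."""
    pool = fit_pairwise_pool(train, spec)
    schedule = es_schedule(len(pool.classes), min_classes=min_classes,
                           mode=mode)
    return ESModel(pool=pool, schedule=schedule, train=train, spec=spec)


def es_predict(model: ESModel, x) -> Prediction:
    """Classify one object by the staged OVO/OVR ensemble.

    All stage subsets are ranked by the stage-1 OVO's votes; each stage
    adds the restricted OVO's winner and the winner of an OVR model over
    the top 3 classes of that OVO.  Max-wins over the subclassifier
    votes decides; an exact tie is broken by an OVR model over the tied
    classes only.
    """
    pool, schedule = model.pool, model.schedule
    votes: dict = {}
    c1 = ovo_predict(pool, x)
    votes["C1"] = c1.winner
    top3 = vote_rank(c1.votes, 3, c1.response_sums, pool.classes)
    _, w = ovr_predict(model.ovr_for(top3), x)
    votes["C2"] = w
    for stage in range(2, schedule.n_stages + 1):
        alpha = schedule.stage_counts[stage - 1]
        subset = vote_rank(c1.votes, alpha, c1.response_sums, pool.classes)
        c_odd = ovo_predict(pool, x, subset)
        votes[f"C{2 * stage - 1}"] = c_odd.winner
        top3 = vote_rank(c_odd.votes, 3, c_odd.response_sums, pool.classes)
        _, w = ovr_predict(model.ovr_for(top3), x)
        votes[f"C{2 * stage}"] = w
    tied = max_wins(votes.values())
    if len(tied) == 1:
        return Prediction(predicted_class=tied[0], votes=votes,
                          tie_broken=False)
    _, w = ovr_predict(model.ovr_for(tied), x)
    return Prediction(predicted_class=w, votes=votes, tie_broken=True)


# ------------------------------------------------------ whole systems --

@dataclass
class MulticlassSystem:
    """A fitted strategy x classifier system with its training scaling.

    Features are auto-scaled with training-set parameters before any
    submodel sees them; prediction applies the same parameters.
    """

    strategy: str                 # "ovr" | "ovo" | "es"
    scaling: ScalingParams
    inner: object                 # OVRModel | PairwisePool | ESModel
    classes: list


def fit_system(train: FeatureTable, strategy: str, spec: BinarySpec,
               min_classes: int = 10) -> MulticlassSystem:
    """Auto-scale the training table and fit one of the three strategies."""
    if train.labels is None:
        raise ValueError("training table has no labels")
    scaling = autoscale_fit(train.values, train.feature_names)
    scaled = FeatureTable(autoscale_apply(train.values, scaling),
                          train.sample_ids, train.feature_names,
                          train.labels)
    cmap = ClassLabelMap.from_labels(train.labels)
    if strategy == "ovr":
        inner = fit_ovr(scaled, cmap.classes, spec)
    elif strategy == "ovo":
        inner = fit_pairwise_pool(scaled, spec)
    elif strategy == "es":
        inner = fit_es(scaled, spec, min_classes=min_classes)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return MulticlassSystem(strategy=strategy, scaling=scaling,
                            inner=inner, classes=cmap.classes)


def predict_sample(system: MulticlassSystem, x) -> Prediction:
    xs = autoscale_apply(np.atleast_2d(x), system.scaling)[0]
    if system.strategy == "ovr":
        _, w = ovr_predict(system.inner, xs)
        return Prediction(predicted_class=w, votes={}, tie_broken=False)
    if system.strategy == "ovo":
        res = ovo_predict(system.inner, xs)
        return Prediction(predicted_class=res.winner, votes={},
                          tie_broken=False)
    return es_predict(system.inner, xs)


def predict_table(system: MulticlassSystem, table: FeatureTable) -> np.ndarray:
    """Predicted class label per row of ``table``."""
    preds = [predict_sample(system, row).predicted_class
             for row in table.values]
    return np.asarray(preds)
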