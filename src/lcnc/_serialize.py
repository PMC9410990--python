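"""JSON round-trips for fitted models (used by the train/predict CLI).

Everything is written as one plain-text JSON document with a ``type``
tag; numpy arrays become nested lists.  The ES on-demand OVR cache is
not persisted — it is rebuilt lazily from the stored training table.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np

from .binary import LSSVMModel, PLSDAModel
from .data_io import FeatureTable
from .model_selection import BinarySpec
from .multiclass import (ESModel, ESSchedule, MulticlassSystem, OVRModel,
                         PairwisePool)
from .preprocessing import ScalingParams

__all__ = ["save_model", "load_model"]


def _arr(x):
    return np.asarray(x).tolist()


def _label(x):
    return x.item() if isinstance(x, np.generic) else x


def _binary_to_dict(model):
    if isinstance(model, PLSDAModel):
        d = asdict(model)
        for k in ("x_center", "x_scale", "weights", "loadings",
                  "y_loadings", "regression_vector"):
            d[k] = _arr(d[k])
        d["type"] = "plsda"
        return d
    if isinstance(model, LSSVMModel):
        d = asdict(model)
        d["alphas"] = _arr(d["alphas"])
        d["support_X"] = _arr(d["support_X"])
        d["type"] = "lssvm"
        return d
    raise TypeError(f"cannot serialize {type(model)!r}")


def _binary_from_dict(d):
    d = dict(d)
    kind = d.pop("type")
    if kind == "plsda":
        for k in ("x_center", "x_scale", "weights", "loadings",
                  "y_loadings", "regression_vector"):
            d[k] = np.asarray(d[k], dtype=float)
        return PLSDAModel(**d)
    if kind == "lssvm":
        d["alphas"] = np.asarray(d["alphas"], dtype=float)
        d["support_X"] = np.asarray(d["support_X"], dtype=float)
        return LSSVMModel(**d)
    raise ValueError(f"unknown binary model type {kind!r}")


def _spec_to_dict(spec: BinarySpec):
    d = asdict(spec)
    for k in ("sigma_grid", "gamma_grid"):
        if d[k] is not None:
            d[k] = _arr(d[k])
    return d


def _spec_from_dict(d):
    d = dict(d)
    for k in ("sigma_grid", "gamma_grid"):
        if d[k] is not None:
            d[k] = tuple(d[k])
    return BinarySpec(**d)


def _table_to_dict(t: FeatureTable):
    return {
        "values": _arr(t.values),
        "sample_ids": list(t.sample_ids),
        "feature_names": list(t.feature_names),
        "labels": None if t.labels is None else [_label(x) for x in t.labels],
    }


def _table_from_dict(d):
    return FeatureTable(
        np.asarray(d["values"], dtype=float), d["sample_ids"],
        d["feature_names"],
        None if d["labels"] is None else np.asarray(d["labels"]),
    )


def _inner_to_dict(inner):
    if isinstance(inner, PairwisePool):
        return {
            "type": "pool",
            "classes": [_label(c) for c in inner.classes],
            "spec": _spec_to_dict(inner.spec),
            "models": [
                {"pos": _label(pos), "neg": _label(neg),
                 "model": _binary_to_dict(m)}
                for _, (m, pos, neg) in sorted(
                    inner.models.items(), key=lambda kv: str(sorted(map(str, kv[0]))))
            ],
        }
    if isinstance(inner, OVRModel):
        return {
            "type": "ovr",
            "classes": [_label(c) for c in inner.classes],
            "spec": _spec_to_dict(inner.spec),
            "models": [{"class": _label(c),
                        "model": _binary_to_dict(inner.models[c])}
                       for c in inner.classes],
        }
    if isinstance(inner, ESModel):
        return {
            "type": "es",
            "pool": _inner_to_dict(inner.pool),
            "schedule": {"stage_counts": inner.schedule.stage_counts,
                         "min_classes": inner.schedule.min_classes},
            "train": _table_to_dict(inner.train),
            "spec": _spec_to_dict(inner.spec),
        }
    raise TypeError(f"cannot serialize {type(inner)!r}")


def _inner_from_dict(d):
    kind = d["type"]
    if kind == "pool":
        models = {}
        for e in d["models"]:
            m = _binary_from_dict(e["model"])
            models[frozenset((e["pos"], e["neg"]))] = (m, e["pos"], e["neg"])
        return PairwisePool(classes=list(d["classes"]), models=models,
                            spec=_spec_from_dict(d["spec"]))
    if kind == "ovr":
        return OVRModel(
            classes=list(d["classes"]),
            models={e["class"]: _binary_from_dict(e["model"])
                    for e in d["models"]},
            spec=_spec_from_dict(d["spec"]),
        )
    if kind == "es":
        return ESModel(
            pool=_inner_from_dict(d["pool"]),
            schedule=ESSchedule(**d["schedule"]),
            train=_table_from_dict(d["train"]),
            spec=_spec_from_dict(d["spec"]),
        )
    raise ValueError(f"unknown model type {kind!r}")


def save_model(system: MulticlassSystem, path) -> None:
    doc = {
        "format": "lcnc-model",
        "version": 1,
        "strategy": system.strategy,
        "classes": [_label(c) for c in system.classes],
        "scaling": {"center": _arr(system.scaling.center),
                    "scale": _arr(system.scaling.scale)},
        "inner": _inner_to_dict(system.inner),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> MulticlassSystem:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "lcnc-model":
        raise ValueError(f"{path}: not a model file")
    scaling = ScalingParams(
        center=np.asarray(doc["scaling"]["center"], dtype=float),
        scale=np.asarray(doc["scaling"]["scale"], dtype=float),
    )
    return MulticlassSystem(strategy=doc["strategy"], scaling=scaling,
                            inner=_inner_from_dict(doc["inner"]),
                            classes=list(doc["classes"]))
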