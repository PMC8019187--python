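"""Single-file JSON model container with bit-exact round-trips.

Floats are written with Python's shortest-repr JSON encoding, which
round-trips IEEE doubles exactly.
"""

from __future__ import annotations

import json

import numpy as np

from .baselines import IndependentMarginals, MICEGenerator, _Regression
from .dbm import DBM
from .rbm import RBM

__all__ = ["save_model", "load_model"]

FORMAT_VERSION = 1


def _tolist(a):
    return np.asarray(a, dtype=float).tolist()


def save_model(model, path) -> None:
    doc = {"format": "boltzgen-model", "format_version": FORMAT_VERSION,
           "params": model.get_params()}
    if isinstance(model, RBM):
        doc["model_type"] = "rbm"
        doc["arrays"] = {"weights": _tolist(model.weights_),
                         "visible_bias": _tolist(model.visible_bias_),
                         "hidden_bias": _tolist(model.hidden_bias_)}
    elif isinstance(model, DBM):
        doc["model_type"] = "dbm"
        doc["arrays"] = {"weights": [_tolist(W) for W in model.weights_],
                         "biases": [_tolist(b) for b in model.biases_]}
    elif isinstance(model, IndependentMarginals):
        doc["model_type"] = "im"
        doc["arrays"] = {"frequencies": _tolist(model.frequencies_)}
    elif isinstance(model, MICEGenerator):
        doc["model_type"] = "mice"
        doc["arrays"] = {
            "order": [int(i) for i in model.order_],
            "first_prob": model.first_prob_,
            "dropped": sorted(int(i) for i in model.dropped_),
            "regressions": [
                {"constant": r.constant,
                 "predictors": [int(p) for p in r.predictors],
                 "coef": None if r.coef is None else _tolist(r.coef),
                 "intercept": r.intercept}
                for r in model.regressions_],
        }
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    doc["feature_names"] = list(getattr(model, "feature_names_", []))
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path):
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "boltzgen-model":
        raise ValueError(f"{path} is not a boltzgen model file")
    if doc.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported format version {doc.get('format_version')}")
    kind = doc["model_type"]
    arrays = doc["arrays"]
    if kind == "rbm":
        model = RBM.from_arrays(arrays["weights"], arrays["visible_bias"],
                                arrays["hidden_bias"])
    elif kind == "dbm":
        model = DBM.from_arrays(arrays["weights"], arrays["biases"])
    elif kind == "im":
        model = IndependentMarginals()
        model.frequencies_ = np.asarray(arrays["frequencies"], dtype=float)
    elif kind == "mice":
        model = MICEGenerator()
        model.order_ = np.asarray(arrays["order"], dtype=int)
        model.first_prob_ = float(arrays["first_prob"])
        model.dropped_ = set(arrays["dropped"])
        model.regressions_ = [
            _Regression(
                constant=r["constant"], predictors=list(r["predictors"]),
                coef=None if r["coef"] is None else np.asarray(r["coef"]),
                intercept=r["intercept"])
            for r in arrays["regressions"]]
    else:
        raise ValueError(f"unknown model type {kind!r}")
    model.set_params(**{k: tuple(v) if isinstance(v, list) else v
                        for k, v in doc["params"].items()})
    if doc.get("feature_names"):
        model.feature_names_ = list(doc["feature_names"])
    return model
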