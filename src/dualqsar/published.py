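"""Frozen published prediction equations and the selectivity classifier.

Model A predicts hTAAR1 pKi from 10 descriptors; model B predicts
α₂-adrenoreceptor pKi from 11.  Both are plain linear equations whose
coefficients were obtained by ISE-PLS on a 31-compound training set and are
shipped verbatim as package data — this module never refits them.  The
selectivity call compares the two predictions: a compound is TAAR1-selective
when its predicted pKi advantage over the adrenoreceptor exceeds a threshold
(default 1 log unit, i.e. ten-fold in Ki).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "LinearModel",
    "SelectivityCall",
    "load_model",
    "load_model_a",
    "load_model_b",
    "predict",
    "relative_importance",
    "selectivity",
    "reproduce_published_fit",
    "MOE_REFERENCE_VALUES",
    "TRAINING_SET_IDS",
    "TEST_SET_IDS",
]

#: Single-compound descriptor values printed alongside the published models,
#: computed with the original proprietary engine (MOE, AM1 charges).  The
#: compound structures are not distributed with the models, so these are
#: documentation constants — loose references for a differently-conventioned
#: descriptor engine, not regression targets.
MOE_REFERENCE_VALUES = {
    "24": {"DipoleY": 0.2702, "DCASA": 23.7212},
    "29": {"DipoleY": 0.2724, "DCASA": 155.0814},
    "22": {"DipoleY": 0.1838, "DCASA": 57.1006},
    "27": {"DipoleY": 0.0533, "DCASA": 160.3320},
    "12": {"Q_VSA_PNEG": 0.1369, "balabanJ": 1.6145,
           "Q_VSA_FHYD": 0.9532, "E_tor": 0.0625},
    "13": {"Q_VSA_PNEG": 0.2738},
    "11": {"balabanJ": 1.7164, "Q_VSA_FHYD": 0.9484, "E_tor": 3.3058},
}


#: published 31/14 training/test memberships of the 45-compound dataset
#: (same split for both models)
TRAINING_SET_IDS = [
    "5b", "5c", "5d", "5e", "6a", "6c", "6d", "12", "13", "15", "16", "18",
    "19", "20", "22", "24", "26", "27", "28", "29", "31", "32", "33", "34",
    "35", "37", "39", "50", "51", "52", "53",
]
TEST_SET_IDS = [
    "5a", "6b", "6e", "11", "14", "17", "21", "23", "25", "30", "36", "38",
    "49", "54",
]


@dataclass
class LinearModel:
    """A frozen linear pKi equation: intercept + Σ coefficient·descriptor."""

    name: str
    response: str
    intercept: float
    coefficients: dict[str, float]
    relative_importance: dict[str, float] = field(default_factory=dict)
    negatively_related: list[str] = field(default_factory=list)
    provenance: str = ""

    def to_json(self, path=None) -> str:
        payload = {
            "name": self.name, "response": self.response,
            "intercept": self.intercept, "coefficients": self.coefficients,
            "relative_importance": self.relative_importance,
            "negatively_related": self.negatively_related,
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "LinearModel":
        data = json.loads(source if isinstance(source, str) else
                          Path(source).read_text())
        return cls(name=data["name"], response=data["response"],
                   intercept=data["intercept"],
                   coefficients=dict(data["coefficients"]),
                   relative_importance=dict(data.get("relative_importance", {})),
                   negatively_related=list(data.get("negatively_related", [])),
                   provenance=data.get("provenance", ""))


@dataclass
class SelectivityCall:
    pki_taar1: float
    pki_adr: float
    delta: float
    label: str  # "TAAR1-selective" | "ADR-selective" | "dual"


def _load_packaged(filename: str) -> LinearModel:
    text = resources.files("dualqsar.data").joinpath(filename).read_text()
    return LinearModel.from_json(text)


def load_model(which: str) -> LinearModel:
    which = which.upper().removeprefix("MODEL_")
    if which == "A":
        return _load_packaged("model_A.json")
    if which == "B":
        return _load_packaged("model_B.json")
    raise ValueError(f"unknown model {which!r}; expected 'A' or 'B'")


def load_model_a() -> LinearModel:
    return load_model("A")


def load_model_b() -> LinearModel:
    return load_model("B")


def predict(model: LinearModel, descriptors: Mapping[str, float]) -> float:
    """Evaluate the frozen equation; extra descriptor entries are ignored."""
    missing = [k for k in model.coefficients if k not in descriptors]
    if missing:
        raise KeyError(f"{model.name} is missing descriptor(s) {missing}")
    return model.intercept + sum(c * float(descriptors[k])
                                 for k, c in model.coefficients.items())


def relative_importance(model: LinearModel) -> list[dict]:
    """Descriptors ranked by relative importance, with association sign."""
    ranked = sorted(model.relative_importance.items(),
                    key=lambda kv: -kv[1])
    return [{"descriptor": name, "ri": ri,
             "sign": "-" if name in model.negatively_related else "+"}
            for name, ri in ranked]


def selectivity(pki_taar1: float, pki_adr: float,
                threshold: float = 1.0) -> SelectivityCall:
    """Classify a compound from its two predicted/measured affinities."""
    if not (np.isfinite(pki_taar1) and np.isfinite(pki_adr)):
        raise ValueError("both pKi values must be finite")
    delta = pki_taar1 - pki_adr
    if delta >= threshold:
        label = "TAAR1-selective"
    elif delta <= -threshold:
        label = "ADR-selective"
    else:
        label = "dual"
    return SelectivityCall(pki_taar1, pki_adr, delta, label)


def reproduce_published_fit(descriptor_table: pd.DataFrame, model: LinearModel,
                            train_ids: list[str], test_ids: list[str],
                            response: str):
    """Refit PLS on a per-compound descriptor table restricted to a frozen
    model's descriptors and report external-validation statistics.

    ``descriptor_table`` must have a ``compound_id`` column, one column per
    model descriptor, and the response column.  This is the entry point for
    checking the published fit statistics once the original per-compound
    supplementary tables are available; it runs equally on synthetic tables.
    """
    from .pls import _best_lv_fit, cross_validate, evaluate

    cols = list(model.coefficients)
    missing = [c for c in cols if c not in descriptor_table.columns]
    if missing:
        raise KeyError(f"descriptor table lacks column(s) {missing}")
    tab = descriptor_table.set_index("compound_id")
    Xtr = tab.loc[train_ids, cols].to_numpy(float)
    ytr = tab.loc[train_ids, response].to_numpy(float)
    Xte = tab.loc[test_ids, cols].to_numpy(float)
    yte = tab.loc[test_ids, response].to_numpy(float)
    fitted, q2 = _best_lv_fit(Xtr, ytr, n_groups=5, lv_cap=10)
    stats = evaluate(fitted, Xte, yte, ytr.mean(), Xtr, ytr)
    stats.r2cv = q2
    # the published RMSE is reported on the training fit
    resid_tr = ytr - fitted.predict(Xtr)
    stats.rmse = float(np.sqrt((resid_tr ** 2).mean()))
    return fitted, stats
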