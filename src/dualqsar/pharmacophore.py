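"""Pharmacophore distance-constraint models and feature matching.

The two shipped models encode the feature arrangements shared by the most
potent ligands of each receptor: PM_A (hTAAR1; aromatic core flanked by
hydrophobes with a donor/acceptor pair) and PM_B (α₂-adrenoreceptor; two
aromatic/hydrophobic cores with a nearby donor/acceptor pair).  A model is a
constraint graph — typed slots plus pairwise distances in Å — not a rigid 3D
template, because the published distance graphs are incomplete.  Matching is
an exhaustive search over class-compatible injective slot assignments,
feasible because feature sets are small.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .descriptors import assign_pharm_types
from .molecule import MoleculeRecord

__all__ = [
    "FEATURE_CLASSES",
    "PharmacophoreFeature",
    "PharmacophoreModel",
    "MatchResult",
    "load_pm_a",
    "load_pm_b",
    "type_features",
    "match",
]

FEATURE_CLASSES = ("Aro", "Hyd", "AroHyd", "Acc", "Don")

#: slot class -> feature classes it accepts
_COMPATIBLE = {
    "Aro": {"Aro", "AroHyd"},
    "Hyd": {"Hyd", "AroHyd"},
    "AroHyd": {"Aro", "Hyd", "AroHyd"},
    "Acc": {"Acc"},
    "Don": {"Don"},
}

_MAX_ASSIGNMENTS = 10 ** 6


@dataclass
class PharmacophoreFeature:
    """A typed feature, either a model slot (no position) or an instance."""

    label: str
    feature_class: str
    position: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        if self.position is not None:
            self.position = np.asarray(self.position, float)
            if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
                raise ValueError("feature position must be a finite 3-vector")


@dataclass
class PharmacophoreModel:
    """Typed feature slots with pairwise distance constraints (Å)."""

    name: str
    slots: dict[str, str]                      # label -> class
    constraints: list[tuple[str, str, float]]  # (slot, slot, distance)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, b, d in self.constraints:
            if a not in self.slots or b not in self.slots:
                raise ValueError(f"constraint ({a},{b}) references unknown slot")
            if d <= 0:
                raise ValueError("constraint distances must be positive")

    def to_json(self, path=None) -> str:
        payload = {"name": self.name, "features": self.slots,
                   "constraints": [{"pair": [a, b], "distance": d}
                                   for a, b, d in self.constraints],
                   **self.metadata}
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PharmacophoreModel":
        data = json.loads(source if isinstance(source, str)
                          else Path(source).read_text())
        constraints = [(c["pair"][0], c["pair"][1], float(c["distance"]))
                       for c in data["constraints"]]
        meta = {k: v for k, v in data.items()
                if k not in ("name", "features", "constraints")}
        return cls(name=data["name"], slots=dict(data["features"]),
                   constraints=constraints, metadata=meta)


@dataclass
class MatchResult:
    matched: bool
    assignment: dict[str, str]          # slot label -> feature label
    deviations: dict[tuple[str, str], float]
    rms_deviation: float


def load_pm_a() -> PharmacophoreModel:
    return PharmacophoreModel.from_json(
        resources.files("dualqsar.data").joinpath("pm_a.json").read_text())


def load_pm_b() -> PharmacophoreModel:
    return PharmacophoreModel.from_json(
        resources.files("dualqsar.data").joinpath("pm_b.json").read_text())


# ---------------------------------------------------------------------------
# feature perception
# ---------------------------------------------------------------------------

def type_features(mol: MoleculeRecord) -> list[PharmacophoreFeature]:
    """Perceive pharmacophore features from a molecule record.

    Aro: centroid of each aromatic ring.  Hyd: centroid of each connected
    group of two or more hydrophobic heavy atoms (aliphatic carbons without
    heteroatom neighbours, plus Cl/Br/I).  Don / Acc: the donor or acceptor
    atom position (an O–H, typed "polar", contributes both).
    """
    types = assign_pharm_types(mol)
    features: list[PharmacophoreFeature] = []
    k = 0

    def add(cls: str, pos: np.ndarray) -> None:
        nonlocal k
        k += 1
        features.append(PharmacophoreFeature(f"f{k}", cls, pos))

    for ring in mol.aromatic_rings:
        add("Aro", np.mean([mol.atoms[i].position for i in ring], axis=0))

    # connected components of hydrophobic atoms
    hyd = {i for i, t in types.items() if t == "hydrophobe"}
    adj = {i: set() for i in hyd}
    for i, j, _ in mol.bonds:
        if i in hyd and j in hyd:
            adj[i].add(j)
            adj[j].add(i)
    seen: set[int] = set()
    for start in sorted(hyd):
        if start in seen:
            continue
        stack, comp = [start], []
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            comp.append(node)
            stack.extend(adj[node] - seen)
        if len(comp) >= 2:  # a lone aliphatic carbon is not a hydrophobe core
            add("Hyd", np.mean([mol.atoms[i].position for i in comp], axis=0))

    # H-bonding perception runs on the element/valence pattern directly, so
    # aromatic N/O (typed "aromatic" for the surface partition) still count
    for i in mol.heavy_indices():
        atom = mol.atoms[i]
        if atom.element not in ("N", "O"):
            continue
        if atom.n_h > 0:
            add("Don", atom.position)
        if atom.element == "O" or (atom.element == "N" and atom.n_h == 0):
            add("Acc", atom.position)
    return features


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def _assignment_deviations(model: PharmacophoreModel,
                           positions: dict[str, np.ndarray]
                           ) -> dict[tuple[str, str], float]:
    out = {}
    for a, b, target in model.constraints:
        observed = float(np.linalg.norm(positions[a] - positions[b]))
        out[(a, b)] = observed - target
    return out


def match(model: PharmacophoreModel, features: Sequence[PharmacophoreFeature],
          tolerance: float = 0.5) -> MatchResult:
    """Best class-compatible assignment of model slots to features.

    Minimizes the RMS deviation over the model's distance constraints;
    ``matched`` requires every constraint within ``tolerance`` Å.  Distances
    only, hence invariant under rigid motion of the feature set.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    slots = list(model.slots)
    candidates = {
        s: [f for f in features
            if f.position is not None
            and f.feature_class in _COMPATIBLE[model.slots[s]]]
        for s in slots
    }
    if any(not c for c in candidates.values()):
        return MatchResult(False, {}, {}, float("inf"))

    n_assign = 1
    for c in candidates.values():
        n_assign *= len(c)
        if n_assign > _MAX_ASSIGNMENTS:
            raise ValueError(
                "assignment space exceeds 10^6; pre-filter the feature set")

    best: tuple[float, dict, dict] | None = None
    for combo in itertools.product(*(candidates[s] for s in slots)):
        if len({id(f) for f in combo}) != len(combo):  # injective only
            continue
        positions = {s: f.position for s, f in zip(slots, combo)}
        devs = _assignment_deviations(model, positions)
        rms = float(np.sqrt(np.mean([d ** 2 for d in devs.values()]))) \
            if devs else 0.0
        if best is None or rms < best[0]:
            best = (rms, {s: f.label for s, f in zip(slots, combo)}, devs)
    if best is None:
        return MatchResult(False, {}, {}, float("inf"))
    rms, assignment, devs = best
    matched = all(abs(d) <= tolerance for d in devs.values())
    return MatchResult(matched, assignment, devs, rms)
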