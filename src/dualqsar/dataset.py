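"""Descriptor-matrix preparation and training/test design.

The workflow mirrors classic chemometric practice: remove predictors that are
constant overall or within any of a fixed number of cancellation groups,
autoscale, project onto the leading principal components, and pick a
representative training set with the Kennard–Stone maximin algorithm run on
the PC scores with the (autoscaled) response appended as an extra column.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QsarTable",
    "SplitAssignment",
    "venetian_blinds",
    "check_constancy",
    "autoscale",
    "pca_scores",
    "kennard_stone_split",
]


@dataclass
class QsarTable:
    """Compound × descriptor matrix with a pKi response vector."""

    compound_ids: list[str]
    X: np.ndarray
    y: np.ndarray
    column_names: list[str]
    scaling_state: str = "none"  # "none" | "autoscaled"
    column_means: Optional[np.ndarray] = None
    column_sds: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n, p = self.X.shape
        if len(self.compound_ids) != n or len(self.y) != n:
            raise ValueError("row count mismatch between ids, X and y")
        if len(self.column_names) != p:
            raise ValueError("column name count does not match X")
        if len(set(self.compound_ids)) != n:
            raise ValueError("duplicate compound ids")
        if len(set(self.column_names)) != p:
            raise ValueError("duplicate column names")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset_rows(self, ids: Sequence[str]) -> "QsarTable":
        index = {c: i for i, c in enumerate(self.compound_ids)}
        rows = [index[c] for c in ids]
        return replace(self, compound_ids=list(ids), X=self.X[rows],
                       y=self.y[rows])

    def to_frame(self, response_name: str = "pKi") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.column_names)
        df.insert(0, "compound_id", self.compound_ids)
        df[response_name] = self.y
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, response: str,
                   id_column: str = "compound_id") -> "QsarTable":
        cols = [c for c in df.columns if c not in (response, id_column)]
        return cls(compound_ids=[str(c) for c in df[id_column]],
                   X=df[cols].to_numpy(float),
                   y=df[response].to_numpy(float),
                   column_names=cols)

    @classmethod
    def read_csv(cls, path, response: str,
                 id_column: str = "compound_id") -> "QsarTable":
        return cls.from_frame(pd.read_csv(path), response, id_column)


@dataclass
class SplitAssignment:
    """Disjoint training/test partition of the compound ids."""

    train_ids: list[str]
    test_ids: list[str]
    method: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")

    def write_csv(self, path) -> None:
        rows = ([(c, "train") for c in self.train_ids]
                + [(c, "test") for c in self.test_ids])
        pd.DataFrame(rows, columns=["compound_id", "set"]).to_csv(
            Path(path), index=False)


def venetian_blinds(n: int, n_groups: int) -> np.ndarray:
    """Deterministic cancellation-group labels: row i -> group i mod n_groups."""
    return np.arange(n) % n_groups


def check_constancy(table: QsarTable, n_groups: int = 5,
                    tol: float = 0.0) -> tuple[QsarTable, dict]:
    """Drop every column constant overall or within any cancellation group.

    Groups are venetian blinds over the stored row order.  Returns the
    filtered table and a removal report; idempotent.
    """
    if n_groups < 2:
        raise ValueError("need at least 2 cancellation groups")
    if table.n < n_groups:
        raise ValueError("fewer rows than cancellation groups")
    labels = venetian_blinds(table.n, n_groups)
    removed: dict[str, str] = {}
    keep = []
    for j, name in enumerate(table.column_names):
        col = table.X[:, j]
        if np.ptp(col) <= tol:
            removed[name] = "constant overall"
            continue
        bad = [g for g in range(n_groups) if np.ptp(col[labels == g]) <= tol]
        if bad:
            removed[name] = f"constant in group(s) {bad}"
        else:
            keep.append(j)
    if not keep:
        raise ValueError("constancy check removed every column")
    filtered = replace(table, X=table.X[:, keep],
                       column_names=[table.column_names[j] for j in keep])
    report = {"n_groups": n_groups, "removed": removed,
              "n_retained": len(keep)}
    return filtered, report


def autoscale(table: QsarTable) -> QsarTable:
    """Column-wise centering and unit-variance (n−1) scaling."""
    means = table.X.mean(axis=0)
    sds = table.X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [table.column_names[j] for j in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant column(s) {bad}; run check_constancy first")
    return replace(table, X=(table.X - means) / sds, scaling_state="autoscaled",
                   column_means=means, column_sds=sds)


def inverse_autoscale(table: QsarTable) -> QsarTable:
    if table.scaling_state != "autoscaled":
        raise ValueError("table is not autoscaled")
    return replace(table, X=table.X * table.column_sds + table.column_means,
                   scaling_state="none", column_means=None, column_sds=None)


def pca_scores(table: QsarTable, n_components: int = 8
               ) -> tuple[np.ndarray, np.ndarray]:
    """Scores of the leading principal components plus explained-variance
    fractions (of total variance), from the SVD of the autoscaled matrix."""
    if table.scaling_state != "autoscaled":
        raise ValueError("pca_scores expects an autoscaled table")
    Xc = table.X - table.X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if n_components > rank:
        import warnings
        warnings.warn(f"n_components={n_components} exceeds rank {rank}; truncating")
        n_components = rank
    scores = U[:, :n_components] * s[:n_components]
    explained = s ** 2 / (s ** 2).sum()
    return scores, explained[:n_components]


def _kennard_stone_order(M: np.ndarray, n_select: int) -> list[int]:
    """Classic Kennard–Stone maximin selection order (ties: lowest index)."""
    d = np.linalg.norm(M[:, None, :] - M[None, :, :], axis=2)
    n = len(M)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    first = sorted((int(i), int(j)))
    selected = list(first)
    remaining = [k for k in range(n) if k not in selected]
    mind = d[:, selected].min(axis=1)
    while len(selected) < n_select:
        best = max(remaining, key=lambda k: (mind[k], -k))
        selected.append(best)
        remaining.remove(best)
        mind = np.minimum(mind, d[:, best])
    return selected


def kennard_stone_split(matrix: np.ndarray, n_train: int,
                        compound_ids: Sequence[str] | None = None,
                        duplex: bool = False) -> SplitAssignment:
    """Kennard–Stone training/test split on the given design matrix.

    ``matrix`` is typically [PC scores ∥ autoscaled response].  Classic mode
    selects the training set by maximin; the duplex variant alternates picks
    between training and test sets.  Deterministic given the matrix.
    """
    M = np.asarray(matrix, float)
    n = len(M)
    if n_train < 2:
        raise ValueError("n_train must be at least 2")
    if n_train >= n:
        raise ValueError("n_train must be smaller than the number of rows")
    ids = [str(i) for i in range(n)] if compound_ids is None else list(compound_ids)

    if not duplex:
        train_idx = _kennard_stone_order(M, n_train)
        test_idx = [k for k in range(n) if k not in set(train_idx)]
    else:
        # duplex: rank everything by KS order, then alternate train/test picks
        order = _kennard_stone_order(M, n)
        train_idx, test_idx = [], []
        for pos, k in enumerate(order):
            if len(train_idx) >= n_train:
                test_idx.append(k)
            elif len(test_idx) >= n - n_train or pos % 2 == 0:
                train_idx.append(k)
            else:
                test_idx.append(k)

    return SplitAssignment(
        train_ids=[ids[k] for k in sorted(train_idx)],
        test_ids=[ids[k] for k in sorted(test_idx)],
        method="kennard-stone-duplex" if duplex else "kennard-stone",
        parameters={"n_train": n_train, "metric": "euclidean",
                    "n_columns": M.shape[1]},
    )
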