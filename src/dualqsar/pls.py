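"""NIPALS partial least squares with iterative stepwise elimination (ISE).

The regression core is a deterministic NIPALS fit on internally autoscaled
data, with coefficients collapsed back to the original scale.  Model
assessment uses leave-group-out cross-validation over fixed venetian-blind
cancellation groups (Q² = 1 − PRESS_cv/TSS).  Variable selection follows the
ISE scheme: each cycle drops the descriptor with the smallest importance

    z_v = |b_v| s_v / Σ_v |b_v| s_v

(b_v the regression coefficient, s_v the descriptor standard deviation) and
refits; the retained cycle maximizes Q².  External validation reports
PRESS, SD and r²_pred = (SD − PRESS)/SD against a held-out test set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dataset import venetian_blinds

__all__ = [
    "PlsModel",
    "IsePlsResult",
    "ValidationStats",
    "fit_pls",
    "cross_validate",
    "importance",
    "isepls",
    "evaluate",
]


@dataclass
class PlsModel:
    """A fitted PLS regression model.

    ``coefficients``/``intercept`` are on the original (unscaled) data scale;
    the latent decomposition (weights/scores/loadings) lives on the
    autoscaled scale used by NIPALS.
    """

    n_latent: int
    column_names: list[str]
    coefficients: np.ndarray
    intercept: float
    x_means: np.ndarray
    x_sds: np.ndarray
    y_mean: float
    y_sd: float
    weights: np.ndarray      # p × a
    scores: np.ndarray       # n × a
    x_loadings: np.ndarray   # p × a
    y_loadings: np.ndarray   # a
    metadata: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        return self.intercept + X @ self.coefficients

    def predict_latent(self, X: np.ndarray) -> np.ndarray:
        """Prediction via the latent decomposition; equals :meth:`predict`."""
        X = np.atleast_2d(np.asarray(X, float))
        E = (X - self.x_means) / self.x_sds
        yhat = np.zeros(len(E))
        for a in range(self.n_latent):
            t = E @ self.weights[:, a]
            yhat += t * self.y_loadings[a]
            E = E - np.outer(t, self.x_loadings[:, a])
        return self.y_mean + self.y_sd * yhat

    def fitted_r2(self, X: np.ndarray, y: np.ndarray) -> float:
        resid = y - self.predict(X)
        tss = ((y - y.mean()) ** 2).sum()
        return 1.0 - (resid ** 2).sum() / tss


@dataclass
class IsePlsResult:
    """Trace of an ISE elimination run and its selected cycle."""

    cycles: list[dict]
    best_cycle: int
    final_descriptors: list[str]

    @property
    def best(self) -> dict:
        return self.cycles[self.best_cycle]


@dataclass
class ValidationStats:
    r2cv: Optional[float] = None
    r2ncv: Optional[float] = None
    rmse: Optional[float] = None
    press: Optional[float] = None
    sd: Optional[float] = None
    r2pred: Optional[float] = None


def _autoscale_xy(X: np.ndarray, y: np.ndarray):
    xm, xs = X.mean(axis=0), X.std(axis=0, ddof=1)
    xs = np.where(xs == 0, 1.0, xs)
    ym, ys = y.mean(), y.std(ddof=1)
    if ys == 0:
        ys = 1.0
    return (X - xm) / xs, (y - ym) / ys, xm, xs, ym, ys


def fit_pls(X: np.ndarray, y: np.ndarray, n_latent: int,
            column_names: Sequence[str] | None = None) -> PlsModel:
    """Deterministic NIPALS PLS1 fit.

    With ``n_latent=0`` the model is the training mean.  Raises if
    ``n_latent`` exceeds min(n−1, p) or the effective rank.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite")
    if n_latent > min(n - 1, p):
        raise ValueError(f"n_latent={n_latent} exceeds min(n-1, p)={min(n-1, p)}")
    names = list(column_names) if column_names is not None else [
        f"x{j}" for j in range(p)]

    E, f, xm, xs, ym, ys = _autoscale_xy(X, y)
    W = np.zeros((p, n_latent))
    T = np.zeros((n, n_latent))
    P = np.zeros((p, n_latent))
    q = np.zeros(n_latent)
    for a in range(n_latent):
        w = E.T @ f
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            raise ValueError(f"n_latent={n_latent} exceeds the rank of X "
                             f"(deflation degenerate at component {a + 1})")
        w /= norm
        t = E @ w
        tt = t @ t
        pvec = E.T @ t / tt
        qa = f @ t / tt
        E = E - np.outer(t, pvec)
        f = f - qa * t
        W[:, a], T[:, a], P[:, a], q[a] = w, t, pvec, qa

    if n_latent == 0:
        b_scaled = np.zeros(p)
    else:
        # collapsed coefficients: B = W (PᵀW)⁻¹ q
        b_scaled = W @ np.linalg.solve(P.T @ W, q)
    coefs = b_scaled * ys / xs
    intercept = ym - xm @ coefs
    return PlsModel(n_latent=n_latent, column_names=names, coefficients=coefs,
                    intercept=float(intercept), x_means=xm, x_sds=xs,
                    y_mean=float(ym), y_sd=float(ys), weights=W, scores=T,
                    x_loadings=P, y_loadings=q)


def max_latent(X: np.ndarray, cap: int = 10) -> int:
    n, p = X.shape
    return max(1, min(cap, n - 2, p, int(np.linalg.matrix_rank(X - X.mean(axis=0)))))


def cross_validate(X: np.ndarray, y: np.ndarray, n_latent: int,
                   n_groups: int = 5) -> float:
    """Leave-group-out Q² over venetian-blind cancellation groups."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if n_groups < 2:
        raise ValueError("need at least 2 CV groups")
    labels = venetian_blinds(len(y), n_groups)
    if min(np.bincount(labels, minlength=n_groups)) < 1:
        raise ValueError("a CV group has no members")
    press = 0.0
    for g in range(n_groups):
        out = labels == g
        a = min(n_latent, max_latent(X[~out]))
        model = fit_pls(X[~out], y[~out], a)
        press += ((y[out] - model.predict(X[out])) ** 2).sum()
    tss = ((y - y.mean()) ** 2).sum()
    return 1.0 - press / tss


def importance(model: PlsModel, column_sds: np.ndarray) -> np.ndarray:
    """ISE importances z_v = |b_v| s_v / Σ |b_v| s_v (sum to 1)."""
    raw = np.abs(model.coefficients) * np.asarray(column_sds, float)
    total = raw.sum()
    if total == 0:
        warnings.warn("all coefficients zero; importances set uniform")
        return np.full(len(raw), 1.0 / len(raw))
    return raw / total


def _best_lv_fit(X, y, n_groups, lv_cap):
    """Pick the latent-variable count maximizing Q²; return (model, q2)."""
    amax = max_latent(X, cap=lv_cap)
    best_a, best_q2 = 1, -np.inf
    for a in range(1, amax + 1):
        q2 = cross_validate(X, y, a, n_groups)
        if q2 > best_q2:
            best_a, best_q2 = a, q2
    return fit_pls(X, y, best_a), best_q2


def isepls(X: np.ndarray, y: np.ndarray, column_names: Sequence[str] | None = None,
           n_groups: int = 5, lv_cap: int = 10) -> IsePlsResult:
    """Iterative stepwise elimination.

    Cycle: fit PLS (latent count chosen by maximizing Q²), compute
    importances, drop the single minimum-importance descriptor (ties: first
    in column order), record Q².  Stops at one descriptor; the returned best
    cycle maximizes Q² (ties: fewer descriptors).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if p < 2:
        raise ValueError("ISE needs at least 2 descriptors")
    names = list(column_names) if column_names is not None else [
        f"x{j}" for j in range(p)]

    active = list(range(p))
    cycles: list[dict] = []
    while True:
        Xa = X[:, active]
        model, q2 = _best_lv_fit(Xa, y, n_groups, lv_cap)
        if not np.isfinite(q2):
            raise ArithmeticError(
                f"non-finite Q² with descriptors {[names[j] for j in active]}")
        z = importance(model, Xa.std(axis=0, ddof=1))
        cycles.append({
            "descriptors": [names[j] for j in active],
            "importances": dict(zip((names[j] for j in active), z)),
            "q2": q2,
            "n_latent": model.n_latent,
        })
        if len(active) == 1:
            break
        drop_local = int(np.argmin(z))  # argmin takes the first minimum
        active.pop(drop_local)

    best = max(range(len(cycles)),
               key=lambda k: (cycles[k]["q2"], k))  # later cycle = fewer vars
    return IsePlsResult(cycles=cycles, best_cycle=best,
                        final_descriptors=cycles[best]["descriptors"])


def evaluate(model: PlsModel, X_test: np.ndarray, y_test: np.ndarray,
             y_train_mean: float, X_train: np.ndarray | None = None,
             y_train: np.ndarray | None = None) -> ValidationStats:
    """External validation statistics.

    PRESS = Σ(y_test − ŷ)², SD = Σ(y_test − ȳ_train)²,
    r²_pred = (SD − PRESS)/SD, RMSE over the test set; r²_ncv (squared
    correlation of fitted vs observed) when training data are supplied.
    """
    y_test = np.asarray(y_test, float).ravel()
    pred = model.predict(X_test)
    press = float(((y_test - pred) ** 2).sum())
    sd = float(((y_test - y_train_mean) ** 2).sum())
    stats = ValidationStats(press=press, sd=sd,
                            rmse=float(np.sqrt(press / len(y_test))))
    if sd > 0:
        stats.r2pred = (sd - press) / sd
    if X_train is not None and y_train is not None:
        y_train = np.asarray(y_train, float).ravel()
        fitted = model.predict(X_train)
        stats.r2ncv = float(np.corrcoef(fitted, y_train)[0, 1] ** 2)
    return stats
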