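"""Synthetic inputs with the statistical structure the pipeline assumes.

``gen_pls_dataset`` draws a latent-factor descriptor matrix — X = T·Pᵀ + E
with a handful of standard-normal factors and sparse loadings — and a pKi
response carried by the same factors, centred in the affinity range the
dual-target dataset spans (pKi ≈ 5.4–8.7, the window implied by printed Ki
values of 2–4250 nM).  The true coefficient vector and its support are
returned so variable-selection recovery can be measured.  ``fixture_sar_table``
packages the individually reported Ki pairs of the dataset compounds;
``gen_pharm_points`` embeds a pharmacophore constraint graph into 3D and
jitters it, for exercising the matcher's tolerance behaviour.

Everything is seed-deterministic: identical spec + seed ⇒ identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from io import StringIO

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .dataset import QsarTable
from .descriptors import ki_to_pki
from .pharmacophore import PharmacophoreFeature, PharmacophoreModel

__all__ = [
    "SyntheticSpec",
    "gen_pls_dataset",
    "fixture_sar_table",
    "fixture_agonist_ec50",
    "gen_pharm_points",
]

#: pKi window implied by the printed Ki extremes (2 nM → 8.70, 4250 nM → 5.37)
RESPONSE_RANGE = (5.4, 8.7)


@dataclass
class SyntheticSpec:
    """Study conditions for the latent-factor generator.

    Defaults emulate the real design: 45 compounds, a ~300-column descriptor
    block driven by a few latent factors, responses in the observed pKi
    window.  ``support_fraction`` is the fraction of descriptors with nonzero
    loadings (the true support of the regression).
    """

    n: int = 45
    p: int = 300
    n_latent: int = 3
    support_fraction: float = 0.3
    x_noise_sd: float = 0.1
    y_noise_sd: float = 0.3
    response_range: tuple[float, float] = RESPONSE_RANGE
    loading_structure: str = "random"  # "random" | "identity"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n, self.p, self.n_latent) <= 0:
            raise ValueError("n, p and n_latent must be positive")
        if self.n <= self.n_latent:
            raise ValueError("need more compounds than latent factors")
        if min(self.x_noise_sd, self.y_noise_sd) < 0:
            raise ValueError("noise sds must be non-negative")
        if self.loading_structure not in ("random", "identity"):
            raise ValueError("loading_structure must be 'random' or 'identity'")


def gen_pls_dataset(spec: SyntheticSpec) -> tuple[QsarTable, dict]:
    """Generate a QSAR table plus the true-parameter record.

    The response is y = c + s·(T q)/σ₀ + f, with the affine constants chosen
    so the noiseless signal spans the configured pKi range (centre at the
    midpoint, ±2 sd covering the window) and the noise sd is exactly
    ``y_noise_sd`` in pKi units.
    """
    n_support = round(spec.support_fraction * spec.p)
    if n_support < spec.n_latent:
        raise ValueError(
            f"support_fraction {spec.support_fraction} leaves {n_support} "
            f"support descriptors, fewer than {spec.n_latent} latent factors")
    rng = np.random.default_rng(spec.seed)

    T = rng.standard_normal((spec.n, spec.n_latent))
    support = np.sort(rng.choice(spec.p, size=n_support, replace=False))
    P = np.zeros((spec.p, spec.n_latent))
    if spec.loading_structure == "identity":
        # one factor per support descriptor: realizes the direct sparse
        # regression y = X beta + noise with uncorrelated support columns,
        # the identifiable setting for variable-selection recovery
        if n_support != spec.n_latent:
            raise ValueError("identity loadings need n_latent == support size")
        P[support, np.arange(n_support)] = 1.0
    else:
        P[support] = rng.standard_normal((n_support, spec.n_latent))
    X = T @ P.T + spec.x_noise_sd * rng.standard_normal((spec.n, spec.p))

    q = rng.uniform(0.5, 1.5, spec.n_latent) * rng.choice([-1, 1], spec.n_latent)
    signal = T @ q
    sigma0 = signal.std(ddof=1)
    lo, hi = spec.response_range
    center, scale = (lo + hi) / 2, (hi - lo) / 4
    y_noise = spec.y_noise_sd * rng.standard_normal(spec.n)
    y = center + scale * signal / sigma0 + y_noise

    # true coefficients: X beta reproduces the noiseless signal exactly
    beta = P @ np.linalg.solve(P.T @ P, q) * scale / sigma0

    table = QsarTable(
        compound_ids=[f"synth{i + 1}" for i in range(spec.n)],
        X=X, y=y,
        column_names=[f"d{j + 1}" for j in range(spec.p)],
        metadata={"generator": "gen_pls_dataset", "spec": vars(spec).copy()},
    )
    truth = {
        "beta": beta,
        "support": support,
        "support_names": [table.column_names[j] for j in support],
        "n_latent": spec.n_latent,
        "scores": T,
        "loadings": P,
        "y_noise": y_noise,
        "x_noise_sd": spec.x_noise_sd,
    }
    return table, truth


def fixture_sar_table() -> pd.DataFrame:
    """The individually reported Ki pairs of the dual-target dataset.

    Columns: compound_id, Ki at hTAAR1 and α₂-ADR (nM, missing where not
    individually reported), the derived pKi values, and a provenance note.
    Range-only statements are deliberately excluded.
    """
    text = resources.files("dualqsar.data").joinpath(
        "sar_affinities.csv").read_text()
    df = pd.read_csv(StringIO(text))
    for src, dst in (("ki_htaar1_nM", "pki_htaar1"),
                     ("ki_a2adr_nM", "pki_a2adr")):
        df[dst] = [round(ki_to_pki(v, "nM"), 2) if pd.notna(v) else np.nan
                   for v in df[src]]
    return df


def fixture_agonist_ec50() -> pd.DataFrame:
    """Functional potencies (EC₅₀, nM) of the reference hTAAR1 agonists."""
    rows = [
        ("guanfacine", 20.0, 25.1, "hTAAR1 measured; alpha2-ADR literature"),
        ("guanabenz", 10.0, 16.32, "hTAAR1 measured; alpha2-ADR literature"),
        ("beta-PEA", 202.0, np.nan, "hTAAR1 reference agonist"),
    ]
    return pd.DataFrame(rows, columns=["compound_id", "ec50_htaar1_nM",
                                       "ec50_a2adr_nM", "provenance"])


def gen_pharm_points(model: PharmacophoreModel, jitter_sd: float = 0.0,
                     seed: int = 0, max_restarts: int = 50
                     ) -> list[PharmacophoreFeature]:
    """Embed a pharmacophore constraint graph into 3D and add jitter.

    The returned features carry the slot labels and classes; before jitter
    their pairwise distances satisfy every constraint to ~1e-8 Å.  Raises if
    the constraint graph cannot be embedded.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    labels = list(model.slots)
    index = {s: k for k, s in enumerate(labels)}
    rng = np.random.default_rng(seed)

    def residuals(flat: np.ndarray) -> np.ndarray:
        pts = flat.reshape(-1, 3)
        return np.array([
            np.linalg.norm(pts[index[a]] - pts[index[b]]) - d
            for a, b, d in model.constraints
        ])

    best = None
    for _ in range(max_restarts):
        x0 = 3.0 * rng.standard_normal(3 * len(labels))
        sol = least_squares(residuals, x0)
        err = np.abs(residuals(sol.x)).max() if model.constraints else 0.0
        if best is None or err < best[0]:
            best = (err, sol.x)
        if err < 1e-8:
            break
    err, flat = best
    if err > 1e-6:
        raise ValueError(
            f"constraint graph of {model.name} could not be embedded "
            f"(best residual {err:.3g} Å)")
    points = flat.reshape(-1, 3)
    points = points + rng.normal(0.0, jitter_sd, points.shape) \
        if jitter_sd > 0 else points
    return [PharmacophoreFeature(label, model.slots[label], points[k])
            for k, label in enumerate(labels)]
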