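"""Molecular descriptors for the dual-target QSAR models.

The 20 unique descriptors used by the two published binding-affinity models
(one descriptor, Q_VSA_FHYD, is shared between them):

* partial-charge VSA: Q_VSA_FHYD, Q_VSA_PNEG, Q_VSA_POL, Q_RPC-
* SlogP-binned VSA: SlogP_VSA3, SlogP_VSA4
* topological: balabanJ, GCUT_SMR_0, GCUT_SMR_1
* conformation-dependent charge: DipoleY, DipoleZ, DCASA
* potential energy: E, E_tor (MMFF94)
* pharmacophore-feature VSA: vsa_other
* grid-field (VolSurf-style, in :mod:`dualqsar.fields`): vsurf_IW4, vsurf_IW5,
  vsurf_ID1, vsurf_ID7, vsurf_EDmin1

Conventions differ from the proprietary engine (MOE/AM1) the models were
originally built with; values printed alongside the published equations are
therefore loose references, not targets.  See docs/methods.md.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.sparse.csgraph import connected_components, shortest_path

from .molecule import MoleculeRecord
from .surface import sasa_per_atom

__all__ = [
    "DESCRIPTOR_REGISTRY",
    "compute_partial_charge_vsa",
    "compute_slogp_vsa",
    "compute_topological",
    "compute_charge_3d",
    "compute_energy",
    "compute_pharm_feature_vsa",
    "assign_pharm_types",
    "canonical_frame",
    "compute_all",
    "ki_to_pki",
]

#: Every descriptor name the package computes, in registry order.
DESCRIPTOR_REGISTRY = (
    "DipoleY", "SlogP_VSA4", "DCASA", "E", "vsurf_IW5", "DipoleZ",
    "Q_VSA_FHYD", "vsurf_EDmin1", "Q_RPC-", "GCUT_SMR_0",
    "Q_VSA_PNEG", "Q_VSA_POL", "SlogP_VSA3", "vsurf_ID7", "vsa_other",
    "vsurf_IW4", "E_tor", "balabanJ", "vsurf_ID1", "GCUT_SMR_1",
)

# elementary charge * Å in Debye
_EA_TO_DEBYE = 4.80320425


def _require_atoms(mol: MoleculeRecord) -> None:
    if len(mol) == 0:
        raise ValueError(f"molecule {mol.id!r} has no atoms")


# ---------------------------------------------------------------------------
# partial-charge and SlogP VSA descriptors
# ---------------------------------------------------------------------------

def compute_partial_charge_vsa(mol: MoleculeRecord) -> dict[str, float]:
    """Q_VSA_FHYD, Q_VSA_PNEG, Q_VSA_POL and Q_RPC-.

    Q_VSA_FHYD and Q_VSA_PNEG are fractions of the total approximate VDW
    surface (atoms with |q| <= 0.2, resp. q < 0); Q_VSA_POL is the
    *unnormalized* surface sum over atoms with non-negative charge; Q_RPC- is
    the most negative charge divided by the sum of negative charges (0 when
    no atom is negative).
    """
    _require_atoms(mol)
    q = mol.charges
    v = mol.surfaces
    total = v.sum()
    if total <= 0:
        raise ValueError(f"molecule {mol.id!r} has non-positive total surface")
    neg = q < 0
    out = {
        "Q_VSA_FHYD": float(v[np.abs(q) <= 0.2].sum() / total),
        "Q_VSA_PNEG": float(v[neg].sum() / total),
        "Q_VSA_POL": float(v[q >= 0].sum()),
    }
    out["Q_RPC-"] = float(q[neg].min() / q[neg].sum()) if neg.any() else 0.0
    return out


def compute_slogp_vsa(mol: MoleculeRecord) -> dict[str, float]:
    """SlogP_VSA3 / SlogP_VSA4: surface sums over L_i in (0, 0.1] / (0.1, 0.15].

    Bin boundaries are lower-exclusive, upper-inclusive.
    """
    _require_atoms(mol)
    L = np.array([a.logp for a in mol.atoms])
    v = mol.surfaces
    return {
        "SlogP_VSA3": float(v[(L > 0.0) & (L <= 0.1)].sum()),
        "SlogP_VSA4": float(v[(L > 0.1) & (L <= 0.15)].sum()),
    }


def slogp_vsa_bins(mol: MoleculeRecord,
                   edges: tuple[float, ...] = (-0.4, -0.2, 0.0, 0.1, 0.15,
                                               0.2, 0.25, 0.3, 0.4)) -> list[float]:
    """Complete SlogP_VSA bin series (half-open bins partitioning the line).

    Bin 0 is (-inf, edges[0]], bin k is (edges[k-1], edges[k]], the last bin
    is (edges[-1], inf); the series sums to the total surface area.
    """
    L = np.array([a.logp for a in mol.atoms])
    v = mol.surfaces
    bounds = (-np.inf, *edges, np.inf)
    return [float(v[(L > lo) & (L <= hi)].sum())
            for lo, hi in zip(bounds[:-1], bounds[1:])]


# ---------------------------------------------------------------------------
# topological descriptors
# ---------------------------------------------------------------------------

def compute_topological(mol: MoleculeRecord) -> dict[str, float]:
    """balabanJ and the two GCUT_SMR eigenvalue descriptors.

    balabanJ = q/(mu+1) * sum over edges (s_i s_j)^(-1/2), with q the edge
    count, mu the cyclomatic number and s_i the distance-matrix row sums of
    the heavy-atom graph.  GCUT_SMR_k are ordered eigenvalues of a
    Burden-style matrix whose diagonal holds the atomic molar-refractivity
    contributions R_i (off-diagonal 0.1*bond order for bonded pairs, 0.001
    otherwise): k=0 the smallest eigenvalue, k=1 the eigenvalue at the 1/3
    position of the ascending spectrum.
    """
    _require_atoms(mol)
    heavy, adj = mol.heavy_graph()
    n = len(heavy)
    if n == 0:
        raise ValueError(f"molecule {mol.id!r} has no heavy atoms")

    ncomp, labels = connected_components((adj > 0).astype(int), directed=False)
    if ncomp > 1:
        comps = [[heavy[i] for i in np.flatnonzero(labels == c)] for c in range(ncomp)]
        raise ValueError(f"heavy-atom graph of {mol.id!r} is disconnected: {comps}")

    # balabanJ on the unweighted graph
    if n == 1:
        balaban = 0.0
    else:
        dist = shortest_path((adj > 0).astype(float), unweighted=True, directed=False)
        s = dist.sum(axis=1)
        edges = [(i, j) for i in range(n) for j in range(i + 1, n) if adj[i, j] > 0]
        q_edges = len(edges)
        mu = q_edges - n + 1
        balaban = q_edges / (mu + 1) * sum((s[i] * s[j]) ** -0.5 for i, j in edges)

    # Burden-style GCUT matrix with R_i on the diagonal
    mr = np.array([mol.atoms[i].mr for i in heavy])
    B = np.full((n, n), 0.001)
    B[adj > 0] = 0.1 * adj[adj > 0]
    np.fill_diagonal(B, mr)
    eig = np.sort(np.linalg.eigvalsh(B))
    k1 = min(math.ceil(n / 3), n - 1)
    return {
        "balabanJ": float(balaban),
        "GCUT_SMR_0": float(eig[0]),
        "GCUT_SMR_1": float(eig[k1]),
    }


# ---------------------------------------------------------------------------
# conformation-dependent charge descriptors
# ---------------------------------------------------------------------------

def canonical_frame(mol: MoleculeRecord) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic inertial frame for dipole components.

    Returns (origin, rotation) such that ``(position - origin) @ rotation``
    expresses coordinates in the canonical frame: principal axes of the
    heavy-atom inertia tensor (unit masses), ordered by descending moment,
    each axis sign-fixed so the atom with the largest absolute projection has
    a positive coordinate (ties broken by atom index).
    """
    heavy = mol.heavy_positions()
    origin = heavy.mean(axis=0)
    centered = heavy - origin
    # unit-mass inertia tensor
    r2 = (centered ** 2).sum(axis=1)
    inertia = np.eye(3) * r2.sum() - centered.T @ centered
    moments, axes = np.linalg.eigh(inertia)
    order = np.argsort(moments)[::-1]
    axes = axes[:, order]
    proj = centered @ axes
    for k in range(3):
        col = proj[:, k]
        lead = int(np.argmax(np.abs(col)))
        if col[lead] < 0:
            axes[:, k] = -axes[:, k]
    return origin, axes


def compute_charge_3d(mol: MoleculeRecord, sasa_points: int = 256) -> dict[str, float]:
    """DipoleY, DipoleZ (Debye, canonical inertial frame) and DCASA (Å²·e).

    DCASA = |CASA+ - CASA-| with CASA± the water-accessible surface area of
    positively/negatively charged atoms weighted by the extreme charge of
    that sign.
    """
    _require_atoms(mol)
    origin, axes = canonical_frame(mol)
    coords = (mol.positions - origin) @ axes
    q = mol.charges
    dipole = _EA_TO_DEBYE * (q[:, None] * coords).sum(axis=0)

    # SASA sampled in the canonical frame, so the numerical surface (and
    # hence DCASA) is exactly invariant under rigid motion of the input
    canonical = mol.transformed(axes.T, -axes.T @ origin)
    sasa = sasa_per_atom(canonical, n_points=sasa_points)
    pos, neg = q > 0, q < 0
    casa_plus = float(sasa[pos].sum() * q[pos].max()) if pos.any() else 0.0
    casa_minus = float(sasa[neg].sum() * abs(q[neg].min())) if neg.any() else 0.0
    return {
        "DipoleY": float(dipole[1]),
        "DipoleZ": float(dipole[2]),
        "DCASA": abs(casa_plus - casa_minus),
    }


# ---------------------------------------------------------------------------
# potential-energy descriptors
# ---------------------------------------------------------------------------

def compute_energy(mol: MoleculeRecord) -> dict[str, float]:
    """E (total MMFF94 potential energy) and E_tor (torsion + out-of-plane),
    both kcal/mol, for the stored conformer.

    Requires the record to carry its source RDKit molecule; values are
    force-field-convention dependent.
    """
    from rdkit.Chem import AllChem

    if mol.rdkit_mol is None:
        raise ValueError(
            f"molecule {mol.id!r} has no attached structure handle; energies "
            "need the force-field-typed molecule (build via from_rdkit)")
    rd = mol.rdkit_mol
    props = AllChem.MMFFGetMoleculeProperties(rd)
    if props is None:
        bad = [a.GetSymbol() for a in rd.GetAtoms()]
        raise ValueError(f"MMFF94 cannot parameterize {mol.id!r} (atoms: {bad})")
    total = AllChem.MMFFGetMoleculeForceField(rd, props).CalcEnergy()
    for term in ("Bond", "Angle", "StretchBend", "VdW", "Ele"):
        getattr(props, f"SetMMFF{term}Term")(False)
    tor = AllChem.MMFFGetMoleculeForceField(rd, props).CalcEnergy()
    return {"E": float(total), "E_tor": float(tor)}


# ---------------------------------------------------------------------------
# pharmacophore-feature VSA
# ---------------------------------------------------------------------------

#: closed set of per-atom pharmacophore types
PHARM_TYPES = ("donor", "acceptor", "polar", "hydrophobe", "aromatic", "other")

_HALOGEN_HYDROPHOBES = {"Cl", "Br", "I"}


def assign_pharm_types(mol: MoleculeRecord) -> dict[int, str]:
    """Assign exactly one pharmacophore type to every heavy atom.

    Rules (in priority order): aromatic atoms -> aromatic; O with H -> polar
    (donor and acceptor); O without H -> acceptor; N with H -> donor; N
    without H -> acceptor; aliphatic carbon with only carbon/hydrogen heavy
    neighbours, and Cl/Br/I -> hydrophobe; anything else -> other.
    """
    neighbours: dict[int, set[int]] = {i: set() for i in range(len(mol))}
    for i, j, _ in mol.bonds:
        neighbours[i].add(j)
        neighbours[j].add(i)
    types: dict[int, str] = {}
    for idx in mol.heavy_indices():
        a = mol.atoms[idx]
        if a.aromatic:
            types[idx] = "aromatic"
        elif a.element == "O":
            types[idx] = "polar" if a.n_h > 0 else "acceptor"
        elif a.element == "N":
            types[idx] = "donor" if a.n_h > 0 else "acceptor"
        elif a.element == "C":
            het = any(mol.atoms[j].is_heavy and mol.atoms[j].element != "C"
                      for j in neighbours[idx])
            types[idx] = "other" if het else "hydrophobe"
        elif a.element in _HALOGEN_HYDROPHOBES:
            types[idx] = "hydrophobe"
        else:
            types[idx] = "other"
    return types


def compute_pharm_feature_vsa(mol: MoleculeRecord) -> dict[str, float]:
    """vsa_other: surface sum over heavy atoms typed 'other'."""
    _require_atoms(mol)
    types = assign_pharm_types(mol)
    return {"vsa_other": float(sum(mol.atoms[i].surface
                                   for i, t in types.items() if t == "other"))}


def pharm_type_vsa_series(mol: MoleculeRecord) -> dict[str, float]:
    """Surface sums per pharmacophore type; partitions the heavy-atom surface."""
    types = assign_pharm_types(mol)
    out = {t: 0.0 for t in PHARM_TYPES}
    for i, t in types.items():
        out[t] += mol.atoms[i].surface
    return out


# ---------------------------------------------------------------------------
# affinity-scale conversion and the one-call driver
# ---------------------------------------------------------------------------

_KI_UNIT_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6,
                    "nM": 1e-9, "pM": 1e-12}


def ki_to_pki(ki: float, unit: str = "nM") -> float:
    """pKi = -log10(Ki in mol/L).  Ki must be positive and carry a unit."""
    if unit not in _KI_UNIT_FACTORS:
        raise ValueError(f"unknown concentration unit {unit!r}; "
                         f"use one of {sorted(_KI_UNIT_FACTORS)}")
    if not (ki > 0):
        raise ValueError(f"Ki must be positive, got {ki!r}")
    return -math.log10(ki * _KI_UNIT_FACTORS[unit])


def compute_all(mol: MoleculeRecord, include_energy: bool = True,
                include_fields: bool = True, grid_spacing: float = 0.5,
                grid_margin: float = 4.0) -> dict[str, float]:
    """All registry descriptors for one molecule, in registry order.

    Energies require the RDKit handle; grid-field descriptors are the slowest
    part and can be switched off for 2D-only work.
    """
    vec: dict[str, float] = {}
    vec.update(compute_partial_charge_vsa(mol))
    vec.update(compute_slogp_vsa(mol))
    vec.update(compute_topological(mol))
    vec.update(compute_charge_3d(mol))
    vec.update(compute_pharm_feature_vsa(mol))
    if include_energy:
        vec.update(compute_energy(mol))
    if include_fields:
        from .fields import compute_vsurf
        vec.update(compute_vsurf(mol, spacing=grid_spacing, margin=grid_margin))
    return {name: vec[name] for name in DESCRIPTOR_REGISTRY if name in vec}
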