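"""Molecule records carrying the per-atom properties the descriptor engine needs.

A :class:`MoleculeRecord` is a plain container: atoms with 3D coordinates,
partial charges ``q_i`` (elementary charges), approximate accessible van der
Waals surface contributions ``v_i`` (Å²), Crippen logP contributions ``L_i``
and molar-refractivity contributions ``R_i``, plus the bond list.  Records can
be built by hand (useful for oracle tests) or derived from an RDKit molecule
with :func:`from_rdkit` / :func:`from_smiles`, which populates every field:

* a single conformer from a seeded ETKDG distance-geometry embed followed by
  MMFF94 minimization,
* Gasteiger (PEOE, iterative electronegativity-equalization) partial charges,
* Labute's connection-table approximation for the ``v_i``,
* Wildman–Crippen atomic contributions for ``L_i`` and ``R_i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

try:  # RDKit is a hard dependency of the package, soft within this module
    from rdkit import Chem
    from rdkit.Chem import AllChem, rdMolDescriptors
except ImportError:  # pragma: no cover
    Chem = None

__all__ = [
    "Atom",
    "MoleculeRecord",
    "from_rdkit",
    "from_smiles",
    "from_sdf",
    "VDW_RADII",
    "RADII_TABLE_VERSION",
]

#: Bondi-style van der Waals radii (Å) used for surface computations.
RADII_TABLE_VERSION = "bondi-1964/v1"
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}
_DEFAULT_RADIUS = 1.70


@dataclass
class Atom:
    """One atom of a molecule record.

    ``surface`` is the approximate accessible VDW surface contribution v_i in
    Å²; ``logp`` and ``mr`` are the Wildman–Crippen atomic contributions L_i
    and R_i.  ``aromatic`` and ``n_h`` support pharmacophore typing without a
    chemistry toolkit in the loop.
    """

    element: str
    position: np.ndarray
    charge: float = 0.0
    surface: float = 0.0
    logp: float = 0.0
    mr: float = 0.0
    aromatic: bool = False
    n_h: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("atom position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"

    @property
    def radius(self) -> float:
        return VDW_RADII.get(self.element, _DEFAULT_RADIUS)


@dataclass
class MoleculeRecord:
    """A molecule with exactly one 3D conformer and per-atom properties."""

    id: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, float]] = field(default_factory=list)
    conformer_energy: Optional[float] = None
    aromatic_rings: list[tuple[int, ...]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    rdkit_mol: Optional[object] = None

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"bond ({i},{j}) references invalid atoms")

    # -- basic views -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def surfaces(self) -> np.ndarray:
        return np.array([a.surface for a in self.atoms])

    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.is_heavy]

    def heavy_positions(self) -> np.ndarray:
        return np.array([self.atoms[i].position for i in self.heavy_indices()])

    def total_surface(self) -> float:
        return float(self.surfaces.sum())

    def heavy_graph(self) -> tuple[list[int], np.ndarray]:
        """Heavy-atom adjacency matrix with bond orders, plus the index map."""
        heavy = self.heavy_indices()
        remap = {orig: k for k, orig in enumerate(heavy)}
        adj = np.zeros((len(heavy), len(heavy)))
        for i, j, order in self.bonds:
            if i in remap and j in remap:
                adj[remap[i], remap[j]] = adj[remap[j], remap[i]] = order
        return heavy, adj

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: Sequence[float] | None = None) -> "MoleculeRecord":
        """Copy of the record with a rigid motion applied to the conformer."""
        rot = np.eye(3) if rotation is None else np.asarray(rotation, float)
        tr = np.zeros(3) if translation is None else np.asarray(translation, float)
        atoms = [
            Atom(a.element, rot @ a.position + tr, a.charge, a.surface,
                 a.logp, a.mr, a.aromatic, a.n_h)
            for a in self.atoms
        ]
        return MoleculeRecord(self.id, atoms, list(self.bonds),
                              self.conformer_energy, list(self.aromatic_rings),
                              dict(self.metadata), rdkit_mol=None)


# -- construction from RDKit ------------------------------------------------

def from_rdkit(mol, mol_id: str = "mol", seed: int = 2023,
               embed: bool = True) -> MoleculeRecord:
    """Build a fully populated record from an RDKit molecule.

    Hydrogens are made explicit; one conformer is produced by a seeded ETKDG
    embed plus MMFF94 minimization unless the molecule already carries one and
    ``embed`` is False.
    """
    if Chem is None:  # pragma: no cover
        raise ImportError("rdkit is required to build records from molecules")
    mol = Chem.AddHs(mol)
    if embed or mol.GetNumConformers() == 0:
        code = AllChem.EmbedMolecule(mol, randomSeed=seed)
        if code != 0:
            raise ValueError(f"conformer embedding failed for {mol_id}")
        AllChem.MMFFOptimizeMolecule(mol, maxIters=2000)
    AllChem.ComputeGasteigerCharges(mol)
    asa_contribs, _implicit_h = rdMolDescriptors._CalcLabuteASAContribs(mol)
    crippen = rdMolDescriptors._CalcCrippenContribs(mol)
    conf = mol.GetConformer()

    atoms = []
    for idx, at in enumerate(mol.GetAtoms()):
        q = at.GetDoubleProp("_GasteigerCharge")
        if not np.isfinite(q):
            q = 0.0
        pos = conf.GetAtomPosition(idx)
        surface = asa_contribs[idx]
        atoms.append(Atom(
            element=at.GetSymbol(),
            position=np.array([pos.x, pos.y, pos.z]),
            charge=q,
            surface=float(surface),
            logp=crippen[idx][0],
            mr=crippen[idx][1],
            aromatic=at.GetIsAromatic(),
            n_h=at.GetTotalNumHs(includeNeighbors=True),
        ))
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
             for b in mol.GetBonds()]
    rings = [tuple(r) for r in mol.GetRingInfo().AtomRings()
             if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in r)]

    energy = None
    props = AllChem.MMFFGetMoleculeProperties(mol)
    if props is not None:
        ff = AllChem.MMFFGetMoleculeForceField(mol, props)
        if ff is not None:
            energy = ff.CalcEnergy()

    return MoleculeRecord(
        id=mol_id, atoms=atoms, bonds=bonds, conformer_energy=energy,
        aromatic_rings=rings,
        metadata={"charge_scheme": "gasteiger-peoe", "embed_seed": seed,
                  "radii_table": RADII_TABLE_VERSION},
        rdkit_mol=mol,
    )


def from_smiles(smiles: str, mol_id: str | None = None, seed: int = 2023) -> MoleculeRecord:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"could not parse SMILES {smiles!r}")
    return from_rdkit(mol, mol_id or smiles, seed=seed)


def from_sdf(path, seed: int = 2023) -> list[MoleculeRecord]:
    """Read an SDF file; conformers in the file are kept (not re-embedded)."""
    records = []
    for k, mol in enumerate(Chem.SDMolSupplier(str(path), removeHs=False)):
        if mol is None:
            continue
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{k}"
        has_conf = mol.GetNumConformers() > 0
        records.append(from_rdkit(mol, mol_id, seed=seed, embed=not has_conf))
    return records
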