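import numpy as np
import pytest

from dualqsar.molecule import Atom, MoleculeRecord, from_smiles


def make_record(mol_id, atoms, bonds=(), rings=()):
    """Build a MoleculeRecord from (element, xyz, q, v, L, R[, aromatic, n_h])
    tuples — the hand-construction path used by oracle tests."""
    built = []
    for spec in atoms:
        element, xyz, q, v, L, R = spec[:6]
        aromatic = spec[6] if len(spec) > 6 else False
        n_h = spec[7] if len(spec) > 7 else 0
        built.append(Atom(element, np.asarray(xyz, float), q, v, L, R,
                          aromatic, n_h))
    return MoleculeRecord(mol_id, built, [tuple(b) for b in bonds],
                          aromatic_rings=[tuple(r) for r in rings])


def linear_chain(n, element="C", spacing=1.54, mr=2.5):
    """n-atom unbranched heavy-atom chain along x (butane-like backbones)."""
    atoms = [(element, (i * spacing, 0.0, 0.0), 0.0, 10.0, 0.0, mr)
             for i in range(n)]
    bonds = [(i, i + 1, 1.0) for i in range(n - 1)]
    return make_record(f"chain{n}", atoms, bonds)


def ring_molecule(n=6, radius=1.54, mr=2.5):
    """n-membered carbon ring in the xy plane."""
    theta = 2 * np.pi * np.arange(n) / n
    atoms = [("C", (radius * np.cos(t), radius * np.sin(t), 0.0),
              0.0, 10.0, 0.0, mr) for t in theta]
    bonds = [(i, (i + 1) % n, 1.0) for i in range(n)]
    return make_record(f"ring{n}", atoms, bonds)


@pytest.fixture(scope="session")
def benzene():
    return from_smiles("c1ccccc1", "benzene", seed=11)


@pytest.fixture(scope="session")
def ethanol():
    return from_smiles("CCO", "ethanol", seed=11)


@pytest.fixture(scope="session")
def imidazole():
    return from_smiles("c1cnc[nH]1", "imidazole", seed=11)


@pytest.fixture(scope="session")
def methane():
    return from_smiles("C", "methane", seed=11)
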