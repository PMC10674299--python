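"""Descriptor engine: summation oracles, hand-computed topological values,
rigid-motion invariance, and the affinity-scale conversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from dualqsar import descriptors as dsc
from dualqsar.fields import compute_vsurf
from dualqsar.molecule import MoleculeRecord
from dualqsar.surface import sasa_per_atom

from conftest import linear_chain, make_record, ring_molecule


def toy3(q=(-0.3, 0.1, 0.2), v=(10.0, 20.0, 30.0), L=(0.0, 0.0, 0.0)):
    atoms = [("C", (float(i), 0.0, 0.0), q[i], v[i], L[i], 2.5)
             for i in range(3)]
    return make_record("toy3", atoms, [(0, 1, 1.0), (1, 2, 1.0)])


class TestPartialChargeVsa:
    def test_direct_summation_oracle(self):
        d = dsc.compute_partial_charge_vsa(toy3())
        assert d["Q_VSA_PNEG"] == pytest.approx(10 / 60)
        assert d["Q_RPC-"] == pytest.approx(1.0)  # single negative atom
        assert d["Q_VSA_FHYD"] == pytest.approx(50 / 60)
        assert d["Q_VSA_POL"] == pytest.approx(50.0)  # unnormalized, printed text

    def test_all_small_charges_give_full_hydrophobic_fraction(self):
        d = dsc.compute_partial_charge_vsa(toy3(q=(0.2, -0.1, 0.05)))
        assert d["Q_VSA_FHYD"] == 1.0

    def test_no_negative_charge_convention(self):
        d = dsc.compute_partial_charge_vsa(toy3(q=(0.1, 0.2, 0.3)))
        assert d["Q_RPC-"] == 0.0
        assert d["Q_VSA_PNEG"] == 0.0

    def test_empty_molecule_rejected(self):
        with pytest.raises(ValueError):
            dsc.compute_partial_charge_vsa(MoleculeRecord("empty", []))

    @given(st.lists(st.tuples(st.floats(-1, 1), st.floats(0.1, 30)),
                    min_size=1, max_size=8))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_fractions_bounded(self, qv):
        atoms = [("C", (i * 1.5, 0.0, 0.0), q, v, 0.0, 2.5)
                 for i, (q, v) in enumerate(qv)]
        mol = make_record("h", atoms, [(i, i + 1, 1.0)
                                       for i in range(len(qv) - 1)])
        d = dsc.compute_partial_charge_vsa(mol)
        assert 0.0 <= d["Q_VSA_FHYD"] <= 1.0
        assert 0.0 <= d["Q_VSA_PNEG"] <= 1.0
        assert 0.0 <= d["Q_RPC-"] <= 1.0


class TestSlogpVsa:
    def test_interval_membership_oracle(self):
        mol = toy3(L=(0.05, 0.10, 0.12), v=(8.0, 12.0, 5.0))
        d = dsc.compute_slogp_vsa(mol)
        assert d["SlogP_VSA3"] == pytest.approx(20.0)  # 0.10 boundary included
        assert d["SlogP_VSA4"] == pytest.approx(5.0)

    def test_zero_logp_contributions_fall_outside_bins(self):
        d = dsc.compute_slogp_vsa(toy3())
        assert d["SlogP_VSA3"] == 0.0 and d["SlogP_VSA4"] == 0.0

    def test_bin_series_partitions_total_surface(self):
        rng = np.random.default_rng(5)
        atoms = [("C", (i * 1.5, 0.0, 0.0), 0.0, v, L, 2.5)
                 for i, (v, L) in enumerate(zip(rng.uniform(1, 20, 12),
                                                rng.normal(0, 0.3, 12)))]
        mol = make_record("rand", atoms,
                          [(i, i + 1, 1.0) for i in range(11)])
        bins = dsc.slogp_vsa_bins(mol)
        assert sum(bins) == pytest.approx(mol.total_surface(), abs=1e-10)


class TestTopological:
    def test_balaban_hand_values(self):
        assert dsc.compute_topological(linear_chain(2))["balabanJ"] == pytest.approx(1.0)
        # butane backbone: row sums (6,4,4,6), J = 3*(2/sqrt(24) + 1/4)
        exact_butane = 3 * (2 / np.sqrt(24) + 0.25)
        assert dsc.compute_topological(linear_chain(4))["balabanJ"] == pytest.approx(exact_butane, abs=1e-10)
        assert exact_butane == pytest.approx(1.9749, abs=5e-4)
        assert dsc.compute_topological(ring_molecule(6))["balabanJ"] == pytest.approx(2.0000, abs=1e-4)

    def test_balaban_networkx_oracle(self):
        import networkx as nx
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = int(rng.integers(4, 10))
            g = nx.random_labeled_tree(n, seed=int(rng.integers(1 << 30)))
            extra = [(int(rng.integers(n)), int(rng.integers(n)))
                     for _ in range(2)]
            g.add_edges_from((a, b) for a, b in extra if a != b)
            atoms = [("C", (i * 1.3, float(i % 2), 0.0), 0.0, 10.0, 0.0, 2.5)
                     for i in range(n)]
            mol = make_record("g", atoms, [(a, b, 1.0) for a, b in g.edges])
            s = {v: sum(d.values())
                 for v, d in dict(nx.all_pairs_shortest_path_length(g)).items()}
            q = g.number_of_edges()
            mu = q - n + 1
            expected = q / (mu + 1) * sum((s[a] * s[b]) ** -0.5
                                          for a, b in g.edges)
            got = dsc.compute_topological(mol)["balabanJ"]
            assert got == pytest.approx(expected, rel=1e-10)

    def test_single_heavy_atom_gcut_degenerates_to_mr(self):
        mol = make_record("one", [("C", (0, 0, 0), 0.0, 10.0, 0.0, 2.5)])
        d = dsc.compute_topological(mol)
        assert d["GCUT_SMR_0"] == pytest.approx(2.5)
        assert d["GCUT_SMR_1"] == pytest.approx(2.5)

    def test_gcut_ordering(self):
        d = dsc.compute_topological(linear_chain(6))
        assert d["GCUT_SMR_0"] <= d["GCUT_SMR_1"]

    def test_disconnected_graph_names_components(self):
        atoms = [("C", (0, 0, 0), 0.0, 10.0, 0.0, 2.5),
                 ("C", (5, 0, 0), 0.0, 10.0, 0.0, 2.5)]
        with pytest.raises(ValueError, match="disconnected"):
            dsc.compute_topological(make_record("two", atoms))

    def test_coordinates_do_not_matter(self):
        mol = linear_chain(5)
        rot = Rotation.from_euler("xyz", [0.3, 1.1, -0.7]).as_matrix()
        moved = mol.transformed(rot, (3.0, -2.0, 8.0))
        assert dsc.compute_topological(mol) == dsc.compute_topological(moved)


class TestCharge3d:
    def test_uncharged_molecule_gives_zero(self):
        d = dsc.compute_charge_3d(ring_molecule(6))
        assert d["DipoleY"] == 0.0 and d["DipoleZ"] == 0.0 and d["DCASA"] == 0.0

    def test_point_charge_dipole_magnitude(self):
        # +-0.5 e separated by 2 Å: |D| = 0.5 * 2 * 4.803 Debye
        atoms = [("C", (0, -1.0, 0), 0.5, 10.0, 0.0, 2.5),
                 ("C", (0, 1.0, 0), -0.5, 10.0, 0.0, 2.5)]
        mol = make_record("dip", atoms, [(0, 1, 1.0)])
        origin, axes = dsc.canonical_frame(mol)
        coords = (mol.positions - origin) @ axes
        q = mol.charges
        dip = 4.80320425 * (q[:, None] * coords).sum(axis=0)
        assert np.linalg.norm(dip) == pytest.approx(4.803, abs=1e-3)

    def test_rigid_motion_invariance(self, ethanol):
        ref = dsc.compute_charge_3d(ethanol)
        rot = Rotation.from_euler("zyx", [1.0, 0.4, -2.0]).as_matrix()
        moved = dsc.compute_charge_3d(ethanol.transformed(rot, (12.0, -5.0, 3.0)))
        assert moved["DipoleY"] == pytest.approx(ref["DipoleY"], abs=1e-6)
        assert moved["DipoleZ"] == pytest.approx(ref["DipoleZ"], abs=1e-6)
        # surface sampling has hard in/out masks: grazing sample points can
        # flip under eigenvector round-off, bounding invariance at ~1e-3 rel
        assert moved["DCASA"] == pytest.approx(ref["DCASA"], rel=1e-3, abs=0.02)

    def test_single_sign_charges_use_zero_for_missing_casa_term(self):
        atoms = [("C", (0, 0, 0), 0.3, 10.0, 0.0, 2.5),
                 ("C", (1.5, 0, 0), 0.1, 10.0, 0.0, 2.5)]
        d = dsc.compute_charge_3d(make_record("pos", atoms, [(0, 1, 1.0)]))
        assert d["DCASA"] > 0  # CASA- term is 0, not an error


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        mol = make_record("one", [("C", (0, 0, 0), 0.0, 10.0, 0.0, 2.5)])
        area = sasa_per_atom(mol)[0]
        assert area == pytest.approx(4 * math.pi * (1.70 + 1.4) ** 2, rel=0.02)

    def test_buried_atom_loses_area(self):
        atoms = [("C", (0, 0, 0), 0.0, 10.0, 0.0, 2.5),
                 ("C", (1.5, 0, 0), 0.0, 10.0, 0.0, 2.5)]
        pair = sasa_per_atom(make_record("pair", atoms, [(0, 1, 1.0)]))
        lone = sasa_per_atom(make_record("one", atoms[:1]))
        assert pair[0] < lone[0]


class TestEnergy:
    def test_torsion_energy_orders_ethane_rotamers(self):
        from rdkit import Chem
        from rdkit.Chem import AllChem, rdMolTransforms
        from dualqsar.molecule import from_rdkit

        energies = {}
        for name, angle in (("staggered", 60.0), ("eclipsed", 0.0)):
            m = Chem.AddHs(Chem.MolFromSmiles("CC"))
            AllChem.EmbedMolecule(m, randomSeed=5)
            AllChem.MMFFOptimizeMolecule(m)
            rdMolTransforms.SetDihedralDeg(m.GetConformer(), 2, 0, 1, 5, angle)
            rec = from_rdkit(m, name, embed=False)
            energies[name] = dsc.compute_energy(rec)["E_tor"]
        assert energies["eclipsed"] > energies["staggered"]

    def test_methane_has_no_torsion_energy(self, methane):
        assert dsc.compute_energy(methane)["E_tor"] == pytest.approx(0.0, abs=1e-8)

    def test_energy_invariant_under_rigid_motion(self, ethanol):
        from rdkit.Chem import rdMolTransforms
        from rdkit import Chem
        from dualqsar.molecule import from_rdkit

        ref = dsc.compute_energy(ethanol)
        moved = Chem.Mol(ethanol.rdkit_mol)
        conf = moved.GetConformer()
        rot = Rotation.from_euler("xyz", [0.5, -1.2, 0.9]).as_matrix()
        for i in range(moved.GetNumAtoms()):
            p = conf.GetAtomPosition(i)
            new = rot @ np.array([p.x, p.y, p.z]) + np.array([5.0, 5.0, 5.0])
            conf.SetAtomPosition(i, new.tolist())
        rec = from_rdkit(moved, "moved", embed=False)
        got = dsc.compute_energy(rec)
        assert got["E"] == pytest.approx(ref["E"], abs=1e-6)
        assert got["E_tor"] == pytest.approx(ref["E_tor"], abs=1e-6)

    def test_record_without_structure_handle_rejected(self):
        with pytest.raises(ValueError, match="handle"):
            dsc.compute_energy(linear_chain(3))


class TestVsurf:
    def test_translation_invariance(self, ethanol):
        ref = compute_vsurf(ethanol)
        moved = compute_vsurf(ethanol.transformed(translation=(10, 10, 10)))
        for key, val in ref.items():
            assert moved[key] == pytest.approx(val, abs=1e-8), key

    def test_single_neutral_atom_is_symmetric(self):
        mol = make_record("one", [("C", (0.1, 0.2, 0.3), 0.0, 10.0, 0.0, 2.5)])
        d = compute_vsurf(mol)
        # barycenter of a spherically symmetric sub-level set sits on the atom
        assert d["vsurf_ID1"] <= 0.5
        assert d["vsurf_EDmin1"] < 0

    def test_empty_sublevel_sets_give_zero(self):
        # a neutral atom's polar field bottoms out at the shallow LJ well
        # (-0.15 kcal/mol), above every hydrophilic threshold
        mol = make_record("one", [("C", (0, 0, 0), 0.0, 10.0, 0.0, 2.5)])
        d = compute_vsurf(mol)
        assert d["vsurf_IW4"] == 0.0 and d["vsurf_IW5"] == 0.0


class TestPharmTypeVsa:
    def test_benzene_has_no_other_atoms(self, benzene):
        assert dsc.compute_pharm_feature_vsa(benzene)["vsa_other"] == 0.0

    def test_type_series_partitions_heavy_surface(self, ethanol):
        series = dsc.pharm_type_vsa_series(ethanol)
        heavy_total = sum(ethanol.atoms[i].surface
                          for i in ethanol.heavy_indices())
        assert sum(series.values()) == pytest.approx(heavy_total, abs=1e-10)

    def test_rule_table_on_toy_molecule(self):
        # C-C-N chain: the terminal C bonded only to C is a hydrophobe, the
        # middle C touches N hence 'other'; vsa_other = that atom's surface
        atoms = [("C", (0, 0, 0), 0.0, 7.0, 0.0, 2.5, False, 3),
                 ("C", (1.5, 0, 0), 0.0, 11.0, 0.0, 2.5, False, 2),
                 ("N", (3.0, 0, 0), -0.3, 9.0, 0.0, 1.8, False, 2)]
        mol = make_record("ccn", atoms, [(0, 1, 1.0), (1, 2, 1.0)])
        types = dsc.assign_pharm_types(mol)
        assert types == {0: "hydrophobe", 1: "other", 2: "donor"}
        assert dsc.compute_pharm_feature_vsa(mol)["vsa_other"] == pytest.approx(11.0)


class TestKiToPki:
    @pytest.mark.parametrize("ki, unit, expected", [
        (6, "nM", 8.22),
        (1, "M", 0.00),
        (202, "nM", 6.69),
        (840, "nM", 6.08),
    ])
    def test_printed_conversions(self, ki, unit, expected):
        assert round(dsc.ki_to_pki(ki, unit), 2) == expected

    def test_rejects_nonpositive_and_unitless(self):
        with pytest.raises(ValueError):
            dsc.ki_to_pki(-1, "nM")
        with pytest.raises(ValueError):
            dsc.ki_to_pki(5, "parsecs")


def test_compute_all_covers_registry(ethanol):
    vec = dsc.compute_all(ethanol)
    assert list(vec) == list(dsc.DESCRIPTOR_REGISTRY)
    assert all(np.isfinite(v) for v in vec.values())
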