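"""Featurization, graph construction and label arithmetic."""

import os

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from apmnet.molgraph import (AtomRecord, BondRecord, ELEMENTS, Molecule,
                             StructureParseError, affinity_to_pka,
                             build_complex, featurize_atom, featurize_bond,
                             load_complex, mol_to_graph,
                             parse_affinity_string, read_index,
                             read_structure, save_complex)
from apmnet.fixtures import make_random_molecule

# group layout: element 0:44, degree 44:55, valence 55:62, charge 62,
# radicals 63, hybridization 64:69, aromatic 69, hydrogens 70:75
GROUPS = {"element": slice(0, 44), "degree": slice(44, 55),
          "valence": slice(55, 62), "hybridization": slice(64, 69),
          "hydrogens": slice(70, 75)}


class TestFeaturizeAtom:
    def test_methane_carbon(self):
        v = featurize_atom(AtomRecord("C", degree=4, explicit_valence=4,
                                      hybridization="SP3", total_hydrogens=4))
        assert v.shape == (75,)
        # exactly one 1 per one-hot group, raw charge/radical slots zero
        for sl in GROUPS.values():
            assert v[sl].sum() == 1.0
        assert v[62] == 0.0 and v[63] == 0.0 and v[69] == 0.0
        assert v[0] == 1.0          # carbon is the first element
        assert v[44 + 4] == 1.0     # degree 4
        assert v[55 + 4] == 1.0     # valence 4
        assert v[70 + 4] == 1.0     # 4 hydrogens

    def test_unknown_element_maps_to_last_slot(self):
        v = featurize_atom(AtomRecord("Xx", degree=0, explicit_valence=0))
        assert v[43] == 1.0 and v[:43].sum() == 0.0

    def test_formal_charge_raw_passthrough(self):
        v = featurize_atom(AtomRecord("O", degree=1, explicit_valence=1,
                                      formal_charge=-1, total_hydrogens=0))
        assert v[62] == -1.0
        assert v[GROUPS["valence"]].sum() == 1.0

    def test_aromatic_flag_and_hybridization(self):
        v = featurize_atom(AtomRecord("C", degree=3, explicit_valence=4,
                                      hybridization="SP2", is_aromatic=True,
                                      total_hydrogens=1))
        assert v[69] == 1.0
        assert v[64 + 1] == 1.0

    def test_out_of_range_counts_clamp_to_top_bin(self, caplog):
        v = featurize_atom(AtomRecord("Fe", degree=12, explicit_valence=6,
                                      total_hydrogens=9))
        assert v[44 + 10] == 1.0 and v[70 + 4] == 1.0
        assert any("clamping" in r.message for r in caplog.records)

    @given(st.sampled_from(ELEMENTS + ("Zq",)),
           st.integers(0, 10), st.integers(0, 6), st.integers(-2, 2),
           st.integers(0, 2),
           st.sampled_from(["SP", "SP2", "SP3", "SP3D", "SP3D2"]),
           st.booleans(), st.integers(0, 4))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_one_hot_groups_always_sum_to_one(self, elem, deg, val, chg,
                                              rad, hyb, arom, nh):
        v = featurize_atom(AtomRecord(elem, deg, val, chg, rad, hyb, arom, nh))
        assert v.shape == (75,)
        for sl in GROUPS.values():
            assert v[sl].sum() == 1.0
        assert v[62] == chg and v[63] == rad


class TestFeaturizeBond:
    @pytest.mark.parametrize("order,conj,ring,expected", [
        ("single", False, False, [1, 0, 0, 0, 0, 0]),
        ("aromatic", True, True, [0, 0, 0, 1, 1, 1]),
        ("triple", True, False, [0, 0, 1, 0, 1, 0]),
        ("double", False, True, [0, 1, 0, 0, 0, 1]),
    ])
    def test_indicator_layout(self, order, conj, ring, expected):
        v = featurize_bond(BondRecord(0, 1, order, conj, ring))
        assert v.tolist() == expected
        assert v[:4].sum() == 1.0  # order flags mutually exclusive


class TestMolToGraph:
    def test_two_atom_molecule(self):
        mol = Molecule(
            atoms=[AtomRecord("C", 1, 1, total_hydrogens=3),
                   AtomRecord("O", 1, 1, total_hydrogens=1)],
            bonds=[BondRecord(0, 1, "single")])
        g = mol_to_graph(mol)
        assert g.n == 2 and g.edge_index.shape == (2, 2)
        assert g.E.shape == (2, 6)
        # both directions carry the same feature row
        assert np.array_equal(g.E[0], g.E[1])

    def test_benzene_edges(self):
        atoms = [AtomRecord("C", 2, 4, hybridization="SP2", is_aromatic=True,
                            total_hydrogens=1) for _ in range(6)]
        bonds = [BondRecord(i, (i + 1) % 6, "aromatic", True, True)
                 for i in range(6)]
        g = mol_to_graph(Molecule(atoms=atoms, bonds=bonds))
        assert g.edge_index.shape[1] == 12
        assert np.array_equal(g.E, np.tile([0, 0, 0, 1, 1, 1], (12, 1)))

    def test_empty_molecule_rejected(self):
        with pytest.raises(StructureParseError):
            mol_to_graph(Molecule(atoms=[], bonds=[], id="empty"))

    @pytest.mark.parametrize("seed", range(5))
    def test_adjacency_matches_bruteforce(self, seed):
        mol = make_random_molecule(10, ("C", "N", "O"), seed)
        g = mol_to_graph(mol)
        # brute-force adjacency straight from the bond records
        expected = np.zeros((10, 10))
        for b in mol.bonds:
            expected[b.i, b.j] = expected[b.j, b.i] = 1.0
        got = np.zeros((10, 10))
        got[g.edge_index[0], g.edge_index[1]] = 1.0
        assert np.array_equal(got, expected)
        assert np.array_equal(got, got.T)
        assert np.all(np.diag(got) == 0)


class TestBuildComplex:
    def test_ligand_indices_offset(self, rng):
        pocket = mol_to_graph(make_random_molecule(5, ("C",), 0))
        ligand = mol_to_graph(make_random_molecule(3, ("C",), 1))
        cg = build_complex(pocket, ligand, label=5.0)
        assert cg.graph.n == 8
        assert cg.n_pocket == 5 and cg.n_ligand == 3
        lig_edges = cg.graph.edge_index[:, pocket.n_edges:]
        assert lig_edges.min() >= 5

    @pytest.mark.parametrize("seed", range(4))
    def test_no_cross_edges_and_counts_preserved(self, seed):
        pocket = mol_to_graph(make_random_molecule(8, ("C", "N"), seed))
        ligand = mol_to_graph(make_random_molecule(5, ("C", "O"), seed + 50))
        cg = build_complex(pocket, ligand)
        ei = cg.graph.edge_index
        crosses = ((ei[0] < cg.n_pocket) != (ei[1] < cg.n_pocket)).sum()
        assert crosses == 0
        assert cg.graph.n == pocket.n + ligand.n
        assert ei.shape[1] == pocket.n_edges + ligand.n_edges
        assert cg.graph.X.shape == (cg.graph.n, 75)


class TestAffinityToPka:
    @pytest.mark.parametrize("value,unit,expected", [
        (1, "nM", 9.0), (1, "M", 0.0), (50, "uM", 4.301029995663981),
        (1, "pM", 12.0)])
    def test_known_conversions(self, value, unit, expected):
        assert affinity_to_pka(value, unit) == pytest.approx(expected,
                                                             abs=1e-9)

    @pytest.mark.parametrize("x", range(13))
    def test_powers_of_ten_roundtrip(self, x):
        assert affinity_to_pka(10.0 ** -x, "M") == pytest.approx(x, abs=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            affinity_to_pka(0.0, "M")
        with pytest.raises(ValueError):
            affinity_to_pka(-1.0, "nM")

    def test_affinity_strings(self):
        assert parse_affinity_string("Kd=1nM") == pytest.approx(9.0)
        assert parse_affinity_string("Ki=50uM") == pytest.approx(4.301, abs=1e-3)
        with pytest.raises(ValueError):
            parse_affinity_string("nonsense")


class TestStructureIO:
    def test_sdf_roundtrip_preserves_topology(self, tmp_path):
        from rdkit import Chem
        from apmnet.fixtures import _to_rdkit
        mol = make_random_molecule(12, ("C", "N", "O", "S"), 9)
        path = str(tmp_path / "lig.sdf")
        w = Chem.SDWriter(path)
        w.write(_to_rdkit(mol))
        w.close()
        back = read_structure(path)
        assert len(back.atoms) == len(mol.atoms)
        key = lambda b: (min(b.i, b.j), max(b.i, b.j), b.order)
        assert sorted(map(key, back.bonds)) == sorted(map(key, mol.bonds))
        # degree / valence / hydrogen bookkeeping survives the file
        for a, b in zip(mol.atoms, back.atoms):
            assert (a.element, a.degree, a.explicit_valence,
                    a.total_hydrogens) == (b.element, b.degree,
                                           b.explicit_valence,
                                           b.total_hydrogens)

    def test_pdb_roundtrip_atom_count(self, tmp_path):
        from rdkit import Chem
        from apmnet.fixtures import _to_rdkit
        mol = make_random_molecule(3, ("C", "O"), 2, allow_double=False)
        path = str(tmp_path / "p.pdb")
        Chem.MolToPDBFile(_to_rdkit(mol), path)
        back = read_structure(path)
        assert len(back.atoms) == 3

    def test_corrupt_file_reports_id(self, tmp_path):
        path = tmp_path / "bad.sdf"
        path.write_text("garbage\n$$$$\n")
        with pytest.raises(StructureParseError) as exc:
            read_structure(str(path), mol_id="1abc")
        assert exc.value.mol_id == "1abc"

    def test_missing_file(self, tmp_path):
        with pytest.raises(StructureParseError):
            read_structure(str(tmp_path / "nope.pdb"))

    def test_cache_roundtrip(self, tmp_path):
        pocket = mol_to_graph(make_random_molecule(6, ("C", "N"), 3))
        ligand = mol_to_graph(make_random_molecule(4, ("C",), 4))
        cg = build_complex(pocket, ligand, label=6.5, complex_id="abcd")
        path = str(tmp_path / "abcd.npz")
        save_complex(cg, path)
        back = load_complex(path)
        assert back.id == "abcd" and back.label == 6.5
        assert np.array_equal(back.graph.X, cg.graph.X)
        assert np.array_equal(back.graph.edge_index, cg.graph.edge_index)
        assert np.array_equal(back.graph.E, cg.graph.E)
        assert (back.n_pocket, back.n_ligand) == (6, 4)

    def test_read_index(self, tmp_path):
        path = tmp_path / "index.dat"
        path.write_text("# header\n"
                        "1abc  2.00  2015  9.00  Kd=1nM\n"
                        "2xyz  1.80  2012  4.30  Ki=50uM\n")
        labels = read_index(str(path))
        assert labels == {"1abc": 9.00, "2xyz": 4.30}
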