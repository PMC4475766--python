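"""Molecular data model, file formats, bond inference, ring/aromaticity."""

import numpy as np
import pytest

from oddkit.errors import CapacityError, ParseError
from oddkit.molio import (Atom, Bond, Molecule, assign_implicit_h, infer_bonds,
                          parse_pdb, parse_pdbqt, parse_sdf, parse_smiles,
                          perceive_aromaticity, perceive_rings, write_pdbqt,
                          write_sdf)

from .conftest import random_molecule
from .oracles import brute_infer_bonds, enumerate_all_cycles

# hand-written V2000 benzene record, checked against the format description:
# six atoms, six type-4 (aromatic) bonds
BENZENE_SDF = """benzene


  6  6  0  0  0  0  0  0  0  0999 V2000
    1.3900    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6950    1.2037    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6950    1.2037    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3900    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6950   -1.2037    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6950   -1.2037    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  4  0
  2  3  4  0
  3  4  4  0
  4  5  4  0
  5  6  4  0
  6  1  4  0
M  END
$$$$
"""


class TestSDF:
    def test_empty_document_gives_empty_list(self):
        assert parse_sdf("") == []

    def test_benzene_type4_bonds_set_aromatic_flags(self):
        mols = parse_sdf(BENZENE_SDF)
        assert len(mols) == 1
        m = mols[0]
        assert m.name == "benzene"
        assert sum(a.aromatic for a in m.atoms) == 6
        assert sum(b.aromatic for b in m.bonds) == 6

    def test_round_trip_preserves_tables(self, rng):
        """parse_sdf(write_sdf(m)) reproduces atoms, coordinates to 4
        decimals, bonds and properties for 100 random molecules."""
        for _ in range(100):
            m = random_molecule(rng)
            out = parse_sdf(write_sdf(m))
            assert len(out) == 1
            m2 = out[0]
            assert [a.element for a in m2.atoms] == [a.element for a in m.atoms]
            assert [a.charge for a in m2.atoms] == [a.charge for a in m.atoms]
            for a, b in zip(m.atoms, m2.atoms):
                np.testing.assert_allclose(a.coords, b.coords, atol=5e-5)
            assert [(b.key(), b.order, b.aromatic) for b in m2.bonds] == \
                   [(b.key(), b.order, b.aromatic) for b in m.bonds]
            assert m2.properties == m.properties

    def test_property_block_written(self):
        m = Molecule(atoms=[Atom("C", np.zeros(3))], properties={"pIC50": "6.5"})
        assert "> <pIC50>" in write_sdf(m)

    def test_capacity_limit(self):
        m = Molecule(atoms=[Atom("C", np.zeros(3)) for _ in range(1000)])
        with pytest.raises(CapacityError):
            write_sdf(m)

    def test_malformed_counts_line_reports_location(self):
        bad = "name\n\n\n  x  y\nM  END\n$$$$\n"
        with pytest.raises(ParseError, match="record 1"):
            parse_sdf(bad)

    def test_truncated_atom_block_reports_line(self):
        bad = "name\n\n\n  3  0  0  0  0  0  0  0  0  0999 V2000\n" \
              "    0.0000    0.0000    0.0000 C   0\n$$$$\n"
        with pytest.raises(ParseError):
            parse_sdf(bad)


class TestPDB:
    def test_water_bond_inferred(self):
        text = ("ATOM      1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\n"
                "ATOM      2  H1  HOH A   1       0.960   0.000   0.000  1.00  0.00           H\n")
        prot = parse_pdb(text)
        assert prot.n_atoms() == 2
        assert len(prot.bonds) == 1

    def test_zn_flagged_metal_and_unbonded(self):
        text = ("HETATM    1 ZN    ZN A   1       0.000   0.000   0.000  1.00  0.00          ZN\n"
                "ATOM      2  O   HOH A   2       3.000   0.000   0.000  1.00  0.00           O\n")
        prot = parse_pdb(text)
        assert prot.metals == [0]
        assert prot.bonds == []  # metals never bond covalently

    def test_short_line_is_parse_error_with_line_number(self):
        with pytest.raises(ParseError, match="line 1"):
            parse_pdb("ATOM      1  O   HOH A   1       0.000\n")

    def test_unknown_element_becomes_x_with_warning(self):
        text = "ATOM      1  Q1  UNK A   1       0.000   0.000   0.000  1.00  0.00           Q\n"
        prot = parse_pdb(text)
        assert prot.atoms[0].element == "X"
        assert prot.warnings

    def test_het_as_ligand_splits_out_non_water_hetatms(self):
        text = ("ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
                "HETATM    2  C1  LIG A   9       8.000   0.000   0.000  1.00  0.00           C\n"
                "HETATM    3  O1  LIG A   9       9.400   0.000   0.000  1.00  0.00           O\n"
                "HETATM    4  O   HOH A  10      20.000   0.000   0.000  1.00  0.00           O\n")
        prot, ligands = parse_pdb(text, het_as_ligand=True)
        assert prot.n_atoms() == 2  # GLY CA + the water stays
        assert len(ligands) == 1
        assert [a.element for a in ligands[0].atoms] == ["C", "O"]
        assert len(ligands[0].bonds) == 1  # C-O at 1.4 Å inferred


class TestInferBonds:
    def test_cc_within_and_beyond_threshold(self):
        a = [Atom("C", np.zeros(3)), Atom("C", np.array([1.54, 0, 0]))]
        assert len(infer_bonds(a)) == 1
        b = [Atom("C", np.zeros(3)), Atom("C", np.array([2.5, 0, 0]))]
        assert infer_bonds(b) == []

    def test_matches_brute_force_on_random_clouds(self, rng):
        for _ in range(20):
            atoms = [Atom(str(rng.choice(["C", "N", "O", "S", "H", "Zn"])),
                          rng.uniform(0, 10, 3)) for _ in range(50)]
            got = {b.key() for b in infer_bonds(atoms)}
            assert got == brute_infer_bonds(atoms)

    def test_empty_input(self):
        assert infer_bonds([]) == []


class TestSMILES:
    def test_ethanol_topology_and_implicit_h(self):
        m = parse_smiles("CCO")
        assert [a.element for a in m.atoms] == ["C", "C", "O"]
        assert [a.implicit_h for a in m.atoms] == [3, 2, 1]
        assert len(m.bonds) == 2 and all(b.order == 1 for b in m.bonds)

    def test_benzene_aromatic_ring(self):
        m = parse_smiles("c1ccccc1")
        assert all(a.aromatic for a in m.atoms)
        assert all(a.implicit_h == 1 for a in m.atoms)
        assert len(perceive_rings(m)) == 1

    def test_ammonium_bracket_atom(self):
        m = parse_smiles("[NH4+]")
        assert m.atoms[0].charge == 1
        assert m.atoms[0].implicit_h == 4

    @pytest.mark.parametrize("smiles,n_atoms,n_bonds", [
        ("C#N", 2, 1),
        ("C=C", 2, 1),
        ("CC(C)C", 4, 3),
        ("c1ccc2ccccc2c1", 10, 11),
        ("[O-]C(=O)C", 4, 3),
    ])
    def test_grammar_subset(self, smiles, n_atoms, n_bonds):
        m = parse_smiles(smiles)
        assert m.n_atoms() == n_atoms
        assert len(m.bonds) == n_bonds

    @pytest.mark.parametrize("bad", ["C1CC", "C(C", "CZr", "C/C=C/C", "[13C]", "[C@H]"])
    def test_malformed_input_raises(self, bad):
        with pytest.raises(ParseError):
            parse_smiles(bad)

    def test_implicit_h_nonnegative_property(self, rng):
        """For neutral organic-subset strings valence arithmetic never goes
        below zero."""
        for s in ["CCCC", "C=CC=C", "c1ccccc1c1ccccc1", "CC(=O)OC", "CSC",
                  "FC(F)(F)C", "N#CC#N", "c1ccncc1", "C%10CC%10"]:
            m = parse_smiles(s)
            assert all(a.implicit_h >= 0 for a in m.atoms)


class TestPDBQT:
    def test_vina_result_remark_becomes_score(self):
        text = ("MODEL 1\n"
                "REMARK VINA RESULT:    -7.1      0.000      0.000\n"
                "ATOM      1  C1  LIG A   1       0.000   0.000   0.000  1.00  0.00    0.000 C \n"
                "ENDMDL\n")
        ps = parse_pdbqt(text)
        assert ps.poses[0].score == -7.1

    def test_three_models_ranked(self):
        model = ("MODEL {k}\nREMARK VINA RESULT:    -{k}.0 0 0\n"
                 "ATOM      1  C1  LIG A   1       0.000   0.000   0.000  1.00  0.00    0.000 C \n"
                 "ENDMDL\n")
        text = "".join(model.format(k=k) for k in (1, 2, 3))
        ps = parse_pdbqt(text)
        assert [p.rank for p in ps.poses] == [1, 2, 3]
        assert [p.score for p in ps.poses] == [-1.0, -2.0, -3.0]

    def test_benzene_write_read_types_and_coords(self):
        m = parse_sdf(BENZENE_SDF)[0]
        text = write_pdbqt(m)
        assert text.count(" A \n") + text.count(" A\n") >= 6  # aromatic C type "A"
        assert "TORSDOF 0" in text
        ps = parse_pdbqt(text)
        assert [a.element for a in ps.poses[0].molecule.atoms] == ["C"] * 6
        got = np.array([a.coords for a in ps.poses[0].molecule.atoms])
        want = np.array([a.coords for a in m.atoms])
        np.testing.assert_allclose(got, want, atol=5e-4)

    def test_polar_h_typed_hd(self):
        m = Molecule(atoms=[Atom("O", np.zeros(3)),
                            Atom("H", np.array([0.96, 0, 0]))],
                     bonds=[Bond(0, 1)])
        assert " HD" in write_pdbqt(m)

    def test_model_without_endmdl_is_error(self):
        with pytest.raises(ParseError, match="ENDMDL"):
            parse_pdbqt("MODEL 1\nATOM      1  C1  LIG A   1       "
                        "0.000   0.000   0.000  1.00  0.00    0.000 C \n")

    def test_model_atom_count_mismatch_is_error(self):
        atom = "ATOM      1  C1  LIG A   1       0.000   0.000   0.000  1.00  0.00    0.000 C \n"
        text = f"MODEL 1\n{atom}ENDMDL\nMODEL 2\n{atom}{atom}ENDMDL\n"
        with pytest.raises(ParseError, match="atoms"):
            parse_pdbqt(text)


class TestRingsAndAromaticity:
    def test_acyclic_has_no_rings(self):
        assert perceive_rings(parse_smiles("CCO")) == []

    def test_benzene_single_six_ring(self):
        rings = perceive_rings(parse_smiles("c1ccccc1"))
        assert len(rings) == 1 and len(rings[0]) == 6

    def test_naphthalene_two_six_rings_vs_exhaustive_enumeration(self):
        m = parse_smiles("c1ccc2ccccc2c1")
        rings = perceive_rings(m)
        assert sorted(len(r) for r in rings) == [6, 6]
        # exhaustive cycle enumeration: the graph has exactly cycles of
        # sizes 6, 6 and 10; an SSSR-equivalent basis takes the two smallest
        assert enumerate_all_cycles(m) == [6, 6, 10]

    def test_ring_output_is_ordered_cycle(self):
        m = parse_smiles("c1ccccc1")
        (ring,) = perceive_rings(m)
        bonded = {b.key() for b in m.bonds}
        for a, b in zip(ring, ring[1:] + ring[:1]):
            assert (min(a, b), max(a, b)) in bonded

    def test_cyclohexane_not_aromatic(self):
        m = perceive_aromaticity(parse_smiles("C1CCCCC1"))
        assert not any(a.aromatic for a in m.atoms)

    def test_kekule_benzene_detected_aromatic(self):
        atoms = [Atom("C", np.zeros(3), implicit_h=1) for _ in range(6)]
        bonds = [Bond(k, (k + 1) % 6, order=2 if k % 2 == 0 else 1) for k in range(6)]
        m = perceive_aromaticity(Molecule(atoms=atoms, bonds=bonds))
        assert all(a.aromatic for a in m.atoms)

    def test_kekule_pyridine_six_pi_electrons(self):
        atoms = [Atom("C", np.zeros(3), implicit_h=1) for _ in range(5)] + \
                [Atom("N", np.zeros(3))]
        bonds = [Bond(k, (k + 1) % 6, order=2 if k % 2 == 0 else 1) for k in range(6)]
        m = perceive_aromaticity(Molecule(atoms=atoms, bonds=bonds))
        assert all(a.aromatic for a in m.atoms)

    def test_cyclobutadiene_fails_huckel(self):
        atoms = [Atom("C", np.zeros(3), implicit_h=1) for _ in range(4)]
        bonds = [Bond(0, 1, 2), Bond(1, 2, 1), Bond(2, 3, 2), Bond(3, 0, 1)]
        m = perceive_aromaticity(Molecule(atoms=atoms, bonds=bonds))
        assert not any(a.aromatic for a in m.atoms)  # 4 pi electrons


class TestAssignImplicitH:
    def test_sdf_round_trip_recovers_h_counts(self):
        m = parse_smiles("CC(=O)O")
        h_before = [a.implicit_h for a in m.atoms]
        for a in m.atoms:
            a.coords = np.zeros(3)
        m2 = parse_sdf(write_sdf(m))[0]
        assign_implicit_h(m2)
        assert [a.implicit_h for a in m2.atoms] == h_before


class TestInvariants:
    def test_parsers_deterministic(self, rng):
        m = random_molecule(rng)
        text = write_sdf(m)
        a = parse_sdf(text)[0]
        b = parse_sdf(text)[0]
        assert [(x.element, tuple(x.coords)) for x in a.atoms] == \
               [(x.element, tuple(x.coords)) for x in b.atoms]

    def test_duplicate_bond_rejected(self):
        atoms = [Atom("C", np.zeros(3)), Atom("C", np.ones(3))]
        with pytest.raises(ValueError, match="duplicate"):
            Molecule(atoms=atoms, bonds=[Bond(0, 1), Bond(1, 0)])

    def test_self_bond_rejected(self):
        with pytest.raises(ValueError):
            Molecule(atoms=[Atom("C", np.zeros(3))], bonds=[Bond(0, 0)])
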