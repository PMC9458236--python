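"""Structure/table readers: round trips, format tolerance, error paths."""

import numpy as np
import pytest

from redplif.mol_io import (
    ParseError,
    read_label_list,
    read_mol2,
    read_pdb,
    read_pdbqt,
    read_vina_poses,
)
from redplif.plif import InteractionType
from redplif.synthetic import (
    PlantedInteractionSpec,
    build_complex,
    make_vina_output,
    write_pdb,
    write_pdbqt,
)


@pytest.fixture
def receptor_ligand():
    return build_complex([
        PlantedInteractionSpec(InteractionType.IONIC_PROTEIN_ANION, 3.0),
        PlantedInteractionSpec(InteractionType.HBOND_PROTEIN_DONOR, 3.0),
    ])


class TestPDB:
    def test_round_trip_atoms_and_residues(self, tmp_path, receptor_ligand):
        receptor, _ = receptor_ligand
        path = write_pdb(receptor, tmp_path / "rec.pdb")
        back = read_pdb(path)
        assert len(back) == len(receptor)
        assert [a.residue_number for a in back.atoms] == [a.residue_number for a in receptor.atoms]
        np.testing.assert_allclose(back.coords(), receptor.coords(), atol=1e-3)

    def test_backbone_flags_survive_round_trip(self, tmp_path, receptor_ligand):
        receptor, _ = receptor_ligand
        back = read_pdb(write_pdb(receptor, tmp_path / "rec.pdb"))
        assert [a.is_backbone for a in back.atoms] == [a.is_backbone for a in receptor.atoms]

    def test_hetatm_ligand_never_backbone(self, tmp_path, receptor_ligand):
        _, ligand = receptor_ligand
        back = read_pdb(write_pdb(ligand, tmp_path / "lig.pdb"))
        assert back.atoms and not any(a.is_backbone for a in back.atoms)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("")
        with pytest.raises(ParseError):
            read_pdb(p)

    def test_malformed_coordinate_names_line(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text("ATOM      1  CA  ALA A   1      xx.xxx   0.000   0.000\n")
        with pytest.raises(ParseError, match="line 1"):
            read_pdb(p)

    def test_first_altloc_kept(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(
            "ATOM      1  CA AALA A   1       1.000   0.000   0.000\n"
            "ATOM      2  CA BALA A   1       2.000   0.000   0.000\n"
        )
        mol = read_pdb(p)
        assert len(mol) == 1 and mol.atoms[0].coords[0] == 1.0


class TestPDBQT:
    def test_charges_round_trip(self, tmp_path, receptor_ligand):
        _, ligand = receptor_ligand
        back = read_pdbqt(write_pdbqt(ligand, tmp_path / "lig.pdbqt"))
        np.testing.assert_allclose(
            [a.partial_charge for a in back.atoms],
            [a.partial_charge for a in ligand.atoms], atol=1e-3,
        )

    def test_receptor_backbone_flags(self, tmp_path, receptor_ligand):
        receptor, _ = receptor_ligand
        back = read_pdbqt(write_pdbqt(receptor, tmp_path / "rec.pdbqt"))
        assert [a.is_backbone for a in back.atoms] == [a.is_backbone for a in receptor.atoms]

    def test_flexibility_tree_records_skipped(self, tmp_path):
        p = tmp_path / "flex.pdbqt"
        p.write_text(
            "ROOT\n"
            "ATOM      1  C1  LIG     1       0.000   0.000   0.000  1.00  0.00     0.050 C \n"
            "ENDROOT\nTORSDOF 0\n"
        )
        mol = read_pdbqt(p)
        assert len(mol) == 1 and mol.atoms[0].partial_charge == pytest.approx(0.05)

    def test_records_without_atoms_error(self, tmp_path):
        p = tmp_path / "noatoms.pdbqt"
        p.write_text("ROOT\nENDROOT\nTORSDOF 0\n")
        with pytest.raises(ParseError):
            read_pdbqt(p)

    def test_missing_charge_column_errors(self, tmp_path):
        p = tmp_path / "nocharge.pdbqt"
        p.write_text("ATOM      1  C1  LIG     1       0.000   0.000   0.000\n")
        with pytest.raises(ParseError, match="charge"):
            read_pdbqt(p)


class TestVinaPoses:
    def test_five_modes_with_scores(self, tmp_path):
        paths = make_vina_output(tmp_path, n_runs=1, n_modes=5, seed=4)
        ps = read_vina_poses(paths[0])
        assert len(ps) == 5
        assert ps.scores == sorted(ps.scores)  # written rank-ordered
        assert all(len(p) == 3 for p in ps.poses)

    def test_single_model(self, tmp_path):
        paths = make_vina_output(tmp_path, n_runs=1, n_modes=1, seed=0)
        assert len(read_vina_poses(paths[0])) == 1

    def test_scores_round_trip_exactly(self, tmp_path):
        paths = make_vina_output(tmp_path, n_runs=1, n_modes=5, seed=7)
        text = paths[0].read_text()
        written = [float(l.split(":")[1].split()[0]) for l in text.splitlines()
                   if l.startswith("REMARK VINA RESULT")]
        assert read_vina_poses(paths[0]).scores == written

    def test_model_without_result_line_errors(self, tmp_path):
        p = tmp_path / "bad.pdbqt"
        p.write_text(
            "MODEL 1\n"
            "ATOM      1  C1  LIG     1       0.000   0.000   0.000  1.00  0.00     0.050 C \n"
            "ENDMDL\n"
        )
        with pytest.raises(ParseError, match="VINA RESULT"):
            read_vina_poses(p)

    @pytest.mark.parametrize("text", [
        "MODEL 1\nMODEL 2\nENDMDL\n",       # nested MODEL
        "ENDMDL\n",                          # ENDMDL without MODEL
        "MODEL 1\nREMARK VINA RESULT: -9.0 0 0\n",  # unterminated
        "",                                  # zero models
    ])
    def test_malformed_model_nesting_errors(self, tmp_path, text):
        p = tmp_path / "bad.pdbqt"
        p.write_text(text)
        with pytest.raises(ParseError):
            read_vina_poses(p)


BENZENE_MOL2 = """@<TRIPOS>MOLECULE
benzene
 6 6 1
SMALL
NO_CHARGES
@<TRIPOS>ATOM
  1 C1  1.390  0.000 0.000 C.ar 1 BNZ 0.000
  2 C2  0.695  1.204 0.000 C.ar 1 BNZ 0.000
  3 C3 -0.695  1.204 0.000 C.ar 1 BNZ 0.000
  4 C4 -1.390  0.000 0.000 C.ar 1 BNZ 0.000
  5 C5 -0.695 -1.204 0.000 C.ar 1 BNZ 0.000
  6 C6  0.695 -1.204 0.000 C.ar 1 BNZ 0.000
@<TRIPOS>BOND
 1 1 2 ar
 2 2 3 ar
 3 3 4 ar
 4 4 5 ar
 5 5 6 ar
 6 6 1 ar
"""


class TestMol2:
    def test_benzene_ring_bonds(self, tmp_path):
        p = tmp_path / "benzene.mol2"
        p.write_text(BENZENE_MOL2)
        mol = read_mol2(p)
        assert len(mol) == 6
        assert len(mol.bonds) == 6
        assert all(order == 1.5 for _, _, order in mol.bonds)
        assert mol.atoms[0].atom_type == "C.ar"

    def test_without_bond_section(self, tmp_path):
        p = tmp_path / "nobonds.mol2"
        p.write_text(BENZENE_MOL2.split("@<TRIPOS>BOND")[0])
        mol = read_mol2(p)
        assert len(mol) == 6 and mol.bonds == []

    def test_truncated_atom_line_errors(self, tmp_path):
        p = tmp_path / "trunc.mol2"
        p.write_text("@<TRIPOS>MOLECULE\nx\n@<TRIPOS>ATOM\n  1 C1 0.0 0.0\n")
        with pytest.raises(ParseError):
            read_mol2(p)

    def test_missing_atom_section_errors(self, tmp_path):
        p = tmp_path / "noatom.mol2"
        p.write_text("@<TRIPOS>MOLECULE\nx\n")
        with pytest.raises(ParseError):
            read_mol2(p)


class TestLabelList:
    def test_three_line_list(self, tmp_path):
        p = tmp_path / "actives.ism"
        p.write_text("CCO cmpd1\nCCN cmpd2\nc1ccccc1 cmpd3\n")
        assert read_label_list(p, 1) == {"cmpd1": 1, "cmpd2": 1, "cmpd3": 1}

    def test_union_of_actives_and_decoys(self, tmp_path):
        a = tmp_path / "a.ism"
        d = tmp_path / "d.ism"
        a.write_text("CCO act1\n")
        d.write_text("CCC dec1\nCCCC dec2\n")
        merged = read_label_list(a, 1) | read_label_list(d, 0)
        assert merged == {"act1": 1, "dec1": 0, "dec2": 0}

    def test_nameless_line(self, tmp_path):
        p = tmp_path / "x.ism"
        p.write_text("CCO\n")
        with pytest.raises(ParseError, match="name"):
            read_label_list(p, 1)
        assert read_label_list(p, 1, auto_name=True) == {"line1": 1}

    def test_duplicates_listed(self, tmp_path):
        p = tmp_path / "dup.ism"
        p.write_text("CCO same\nCCN same\n")
        with pytest.raises(ParseError, match="same"):
            read_label_list(p, 1)
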