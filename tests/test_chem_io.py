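import numpy as np
import pytest

import lrdock as L
from lrdock.chem_io import associate_hydrogens
from lrdock.errors import (EmptyStructureError, MissingHydrogensError,
                           ParameterLookupError, ShapeError, ValidationError)
from lrdock.fixtures import make_random_cloud

ONE_ATOM = """\
ATOM      1  CA  GLY A   1       1.250  -2.500   3.750  1.00  0.00           C
END
"""

MULTI_MODEL = """\
MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.400   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.100   1.300   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       3.300   1.300   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       2.100  -1.300   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1       9.000   9.000   9.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       9.400   9.000   9.000  1.00  0.00           C
ATOM      3  C   ALA A   1       9.100   9.300   9.000  1.00  0.00           C
ATOM      4  O   ALA A   1       9.300   9.300   9.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       9.100   9.300   9.000  1.00  0.00           C
ENDMDL
END
"""

ALTLOC = """\
ATOM      1  CA AGLY A   1       0.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BGLY A   1       5.000   0.000   0.000  0.60  0.00           C
END
"""

MMCIF = """\
data_test
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_asym_id
_atom_site.pdbx_PDB_model_num
ATOM 1 N N . ALA A 1 1 ? 1.000 2.000 3.000 1.00 0.00 1 A 1
ATOM 2 C CA . ALA A 1 1 ? 2.500 2.000 3.000 1.00 0.00 1 A 1
"""


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadStructure:
    def test_single_atom_fields_copied(self, tmp_path):
        mol = L.read_structure(_write(tmp_path, "one.pdb", ONE_ATOM))
        assert len(mol) == 1
        a = mol.atoms[0]
        assert (a.serial, a.name, a.residue_name, a.chain) == (1, "CA", "GLY", "A")
        assert np.allclose(a.position, [1.25, -2.5, 3.75])

    def test_first_model_only(self, tmp_path):
        mol = L.read_structure(_write(tmp_path, "mm.pdb", MULTI_MODEL))
        assert len(mol) == 5
        assert np.allclose(mol.atoms[0].position, [0, 0, 0])

    def test_highest_occupancy_altloc_kept(self, tmp_path):
        mol = L.read_structure(_write(tmp_path, "alt.pdb", ALTLOC))
        assert len(mol) == 1
        assert mol.atoms[0].position[0] == pytest.approx(5.0)

    def test_mmcif(self, tmp_path):
        mol = L.read_structure(_write(tmp_path, "t.cif", MMCIF))
        assert len(mol) == 2
        assert mol.atoms[1].name == "CA"
        assert np.allclose(mol.atoms[0].position, [1, 2, 3])

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(IOError):
            L.read_structure(tmp_path / "nope.pdb")

    def test_empty_structure_raises(self, tmp_path):
        with pytest.raises((EmptyStructureError, IOError)):
            L.read_structure(_write(tmp_path, "empty.pdb", "END\n"))


class TestWritePdb:
    def test_round_trip_preserves_fields(self, tmp_path):
        mol = make_random_cloud(50, box=30.0, seed=5)
        path = tmp_path / "rt.pdb"
        L.write_pdb(mol, path)
        back = L.read_structure(path)
        assert len(back) == 50
        assert np.abs(back.positions - mol.positions).max() < 1e-3
        for a, b in zip(mol.atoms, back.atoms):
            assert (a.serial, a.name, a.residue_name, a.chain) == \
                   (b.serial, b.name, b.residue_name, b.chain)

    def test_merged_count_conserved(self, tmp_path, toy_pair):
        rec, lig = toy_pair
        from lrdock.session import Session
        merged = Session(rec, lig, collision_mode="overlap").merge_complex()
        path = tmp_path / "c.pdb"
        L.write_pdb(merged, path)
        assert len(L.read_structure(path)) == len(rec) + len(lig)

    def test_empty_molecule_refused(self, tmp_path):
        from lrdock.chem_io import Molecule
        with pytest.raises(EmptyStructureError):
            L.write_pdb(Molecule([]), tmp_path / "e.pdb")


class TestAssignParameters:
    def test_water_donor_acceptor(self, water_pdb):
        mol = L.read_structure(water_pdb)
        L.assign_parameters(mol)
        o = mol.atoms[0]
        assert o.is_donor and o.is_acceptor
        assert o.bonded_hydrogens == [1, 2]
        assert o.charge == pytest.approx(-0.82)
        assert all(a.vdw_radius > 0 for a in mol.atoms)

    def test_zero_charge_atom_contributes_no_coulomb(self, water_pdb):
        mol = L.read_structure(water_pdb)
        L.assign_parameters(mol)
        probe = make_random_cloud(1, box=1.0, seed=0)
        probe.atoms[0].position = np.array([3.0, 0.0, 0.0])
        probe._invalidate()
        e, f = L.pair_coulomb(3.0, 0.0, probe.charges[0])
        assert e == 0.0 and f == 0.0

    def test_strict_unknown_atom_names_offender(self, tmp_path):
        bad = ONE_ATOM.replace(" CA ", " XX ")
        mol = L.read_structure(_write(tmp_path, "bad.pdb", bad))
        with pytest.raises(ParameterLookupError) as exc:
            L.assign_parameters(mol, policy="strict")
        assert "XX" in str(exc.value)

    def test_lenient_uses_element_fallback(self, tmp_path):
        bad = ONE_ATOM.replace(" CA ", " XX ")
        mol = L.read_structure(_write(tmp_path, "bad.pdb", bad))
        L.assign_parameters(mol, policy="lenient")
        assert mol.atoms[0].vdw_radius == pytest.approx(1.70)  # carbon
        assert mol.atoms[0].charge == 0.0

    def test_assignment_is_deterministic(self, water_pdb):
        m1 = L.read_structure(water_pdb)
        m2 = L.read_structure(water_pdb)
        L.assign_parameters(m1)
        L.assign_parameters(m2)
        assert np.array_equal(m1.charges, m2.charges)
        assert np.array_equal(m1.lj_c6, m2.lj_c6)
        assert np.array_equal(m1.lj_c12, m2.lj_c12)


class TestHydrogenAssociation:
    def test_each_hydrogen_assigned_to_nearest_heavy(self, water_pdb):
        mol = L.read_structure(water_pdb)
        bonded = associate_hydrogens(mol)
        assert bonded == {0: [1, 2]}
        assert mol.unbonded_hydrogens == []

    def test_orphan_hydrogen_flagged_not_dropped(self, tmp_path):
        text = (
            "ATOM      1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\n"
            "ATOM      2  H1  HOH A   1       5.000   0.000   0.000  1.00  0.00           H\n"
            "END\n")
        mol = L.read_structure(_write(tmp_path, "orp.pdb", text))
        bonded = associate_hydrogens(mol)
        assert bonded == {}
        assert mol.unbonded_hydrogens == [1]
        assert len(mol) == 2

    def test_conect_overrides_distance(self, tmp_path):
        # H sits 1.0 A from O but CONECT binds it to N at 1.2 A
        text = (
            "ATOM      1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\n"
            "ATOM      2  N   HOH A   1       2.200   0.000   0.000  1.00  0.00           N\n"
            "ATOM      3  H1  HOH A   1       1.000   0.000   0.000  1.00  0.00           H\n"
            "CONECT    2    3\n"
            "END\n")
        mol = L.read_structure(_write(tmp_path, "cn.pdb", text))
        bonded = associate_hydrogens(mol)
        assert bonded == {1: [2]}


class TestResponseModelIO:
    def _model(self, n3=9, m=2, seed=0):
        rng = np.random.default_rng(seed)
        Q, _ = np.linalg.qr(rng.normal(size=(n3, m)))
        return L.ResponseModel(r_o=rng.normal(size=n3), V=Q,
                               lambdas=np.array([2.0, 0.5]), beta=0.4)

    def test_round_trip(self, tmp_path):
        model = self._model()
        L.write_response_model(model, tmp_path / "ev", tmp_path / "vec")
        back = L.read_response_model(tmp_path / "ev", tmp_path / "vec",
                                     model.r_o, temperature=300.0)
        assert np.abs(back.lambdas - model.lambdas).max() < 1e-10
        assert np.abs(back.V - model.V).max() < 1e-10

    def test_single_mode_closed_form(self, tmp_path):
        (tmp_path / "ev").write_text("1.0\n")
        (tmp_path / "vec").write_text("1 0 0 0 0 0\n")
        model = L.read_response_model(tmp_path / "ev", tmp_path / "vec",
                                      np.zeros(6), temperature=300.0)
        f = np.zeros(6)
        f[0] = 1.0
        dr = L.displacement(model, f)
        assert dr[0] == pytest.approx(model.beta * 1.0)
        assert np.all(dr[1:] == 0)

    def test_wrong_row_length_raises(self, tmp_path):
        (tmp_path / "ev").write_text("1.0\n")
        (tmp_path / "vec").write_text("1 0 0 0 0\n")  # 3N-1 entries
        with pytest.raises(ShapeError):
            L.read_response_model(tmp_path / "ev", tmp_path / "vec", np.zeros(6))

    def test_negative_eigenvalue_raises(self, tmp_path):
        (tmp_path / "ev").write_text("-1.0\n")
        (tmp_path / "vec").write_text("1 0 0 0 0 0\n")
        with pytest.raises(ValidationError):
            L.read_response_model(tmp_path / "ev", tmp_path / "vec", np.zeros(6))


def test_ensemble_text_round_trip(tmp_path):
    rng = np.random.default_rng(3)
    ens = rng.normal(size=(4, 12))
    L.write_ensemble(ens, tmp_path / "ens.txt")
    back = L.read_ensemble(tmp_path / "ens.txt")
    assert np.abs(back - ens).max() < 1e-9
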