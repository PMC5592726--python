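"""Structure parsing, distance primitives and bundle geometry."""


import numpy as np
import pytest

from gpcreval.errors import EmptySelectionError, PdbParseError, ValidationError
from gpcreval.structure_model import (
    Atom,
    Residue,
    StructureModel,
    VdwTable,
    bundle_axis,
    min_heavy_atom_distance,
    parse_structure,
    write_pdb,
)
from tests.conftest import oracle_min_distance

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  CB  ALA A   1      12.919   6.885  -5.032  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA ASER A   1       1.000   0.000   0.000  0.60  0.00           C
ATOM      3  CA BSER A   1       2.000   0.000   0.000  0.40  0.00           C
END
"""


def _res(name3, atoms):
    return Residue(chain="A", seqnum=1, icode="", name3=name3, atoms=atoms)


def _atom(name, element, x, y, z):
    return Atom(serial=1, name=name, element=element, coords=(x, y, z))


class TestParsing:
    def test_minimal_pdb(self):
        s = parse_structure(MINIMAL_PDB)
        assert len(s.residues) == 1
        assert len(s.residues[0].atoms) == 3
        assert s.residues[0].name3 == "ALA"
        assert not s.ligands

    def test_altloc_highest_occupancy_kept(self):
        s = parse_structure(ALTLOC_PDB, altloc_policy="highest_occupancy")
        ca = s.residues[0].atom("CA")
        assert ca.altloc == "A"
        assert ca.coords[0] == pytest.approx(1.0)

    def test_malformed_coordinate_names_line(self):
        bad = MINIMAL_PDB.replace("11.639", "11.6X9")
        with pytest.raises(PdbParseError, match="line 2"):
            parse_structure(bad)

    def test_empty_structure_rejected(self):
        with pytest.raises(PdbParseError):
            parse_structure("END\n")

    def test_waters_dropped_hetero_kept(self):
        pdb = MINIMAL_PDB.replace("END\n", "") + (
            "HETATM    4  O   HOH A 101      20.000  20.000  20.000  1.00  0.00           O\n"
            "HETATM    5  C1  LIG B   1       5.000   5.000   5.000  1.00  0.00           C\n"
            "END\n"
        )
        s = parse_structure(pdb)
        assert [r.name3 for r in s.ligands] == ["LIG"]

    def test_roundtrip_preserves_counts_and_coords(self, default_complex):
        structure, _, _ = default_complex
        reparsed = parse_structure(write_pdb(structure))
        assert len(reparsed.residues) == len(structure.residues)
        for r1, r2 in zip(structure.residues, reparsed.residues):
            assert r1.rid == r2.rid and r1.name3 == r2.name3
            assert [a.name for a in r1.atoms] == [a.name for a in r2.atoms]
            for a1, a2 in zip(r1.atoms, r2.atoms):
                assert np.allclose(a1.coords, a2.coords, atol=1e-3)
        assert len(reparsed.ligands) == len(structure.ligands)


class TestMinDistance:
    def test_three_four_five_triangle(self):
        a = _res("ALA", [_atom("CB", "C", 0, 0, 0)])
        b = _res("ALA", [_atom("CB", "C", 3, 4, 0)])
        assert min_heavy_atom_distance(a, b) == pytest.approx(5.0)

    def test_identity_is_zero(self):
        a = _res("ALA", [_atom("CB", "C", 1, 2, 3)])
        assert min_heavy_atom_distance(a, a) == pytest.approx(0.0)

    def test_matches_bruteforce_on_random_residues(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            atoms_a = [_atom(f"C{i}", "C", *rng.uniform(-5, 5, 3)) for i in range(10)]
            atoms_b = [_atom(f"C{i}", "C", *rng.uniform(-5, 5, 3)) for i in range(10)]
            a, b = _res("LIG", atoms_a), _res("LIG", atoms_b)
            got = min_heavy_atom_distance(a, b)
            assert got == pytest.approx(oracle_min_distance(a, b))
            # symmetry
            assert got == pytest.approx(min_heavy_atom_distance(b, a))

    def test_hydrogens_ignored(self):
        a = _res("ALA", [_atom("CB", "C", 0, 0, 0), _atom("HB1", "H", 2.9, 0, 0)])
        b = _res("ALA", [_atom("CB", "C", 3, 0, 0)])
        assert min_heavy_atom_distance(a, b) == pytest.approx(3.0)

    def test_sidechain_filter_empty_selection(self):
        gly = _res("GLY", [_atom("N", "N", 0, 0, 0), _atom("CA", "C", 1, 0, 0)])
        other = _res("ALA", [_atom("CB", "C", 5, 0, 0)])
        with pytest.raises(EmptySelectionError):
            min_heavy_atom_distance(gly, other, atom_filter="sidechain_only")

    def test_subset_monotonicity(self):
        # min over all atoms <= min over the side-chain subset
        a = _res("SER", [_atom("CA", "C", 0, 0, 0), _atom("OG", "O", 0, 0, 2)])
        b = _res("SER", [_atom("CA", "C", 1, 0, 0), _atom("OG", "O", 4, 0, 0)])
        assert min_heavy_atom_distance(a, b) <= min_heavy_atom_distance(
            a, b, atom_filter="sidechain_only"
        )


class TestBundleAxis:
    @staticmethod
    def _line_structure(n=6):
        residues = [
            Residue(chain="A", seqnum=i + 1, icode="", name3="ALA",
                    atoms=[_atom("CA", "C", 0, 0, float(i))])
            for i in range(n)
        ]
        return StructureModel(id="line", residues=residues)

    def test_line_along_z(self):
        s = self._line_structure()
        axis, centroid = bundle_axis(s, set(range(1, 7)))
        assert abs(axis @ np.array([0, 0, 1])) > 1 - 1e-9
        assert centroid == pytest.approx([0, 0, 2.5])
        # sign convention: residue 1 (z=0) is below the centroid -> axis points -z
        assert axis[2] < 0

    def test_rigid_rotation_equivariance(self):
        rng = np.random.default_rng(3)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        s = self._line_structure()
        axis0, _ = bundle_axis(s, set(range(1, 7)))
        rotated = StructureModel(id="rot", residues=[
            Residue(chain="A", seqnum=r.seqnum, icode="", name3=r.name3,
                    atoms=[Atom(serial=1, name="CA", element="C",
                                coords=tuple(q @ np.asarray(r.atoms[0].coords)))])
            for r in s.residues
        ])
        axis1, _ = bundle_axis(rotated, set(range(1, 7)))
        assert np.allclose(q @ axis0, axis1, atol=1e-6)

    def test_synthetic_bundle_axis_is_z(self, default_complex):
        structure, _, _ = default_complex
        axis, _ = bundle_axis(structure, {r.rid for r in structure.residues})
        assert abs(axis @ np.array([0.0, 0.0, 1.0])) > 0.99
        # helix 1 starts extracellular (+z): orientation must point up
        assert axis[2] > 0

    def test_degenerate_coordinates_rejected(self):
        residues = [
            Residue(chain="A", seqnum=i + 1, icode="", name3="ALA",
                    atoms=[_atom("CA", "C", 1, 1, 1)])
            for i in range(4)
        ]
        s = StructureModel(id="point", residues=residues)
        with pytest.raises(ValidationError):
            bundle_axis(s, set(range(1, 5)))


class TestVdwTable:
    def test_unknown_element_falls_back_to_name(self):
        table = VdwTable()
        odd = _atom("CL7", "Q", 0, 0, 0)
        assert table.radius(odd) == table.radii["C"]

    def test_missing_required_element_rejected(self):
        with pytest.raises(ValidationError):
            VdwTable(radii={"C": 1.7})
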