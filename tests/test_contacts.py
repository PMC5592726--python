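"""Ligand-contact detection, interaction typing, and contact maps."""

import numpy as np
import pytest

from gpcreval.contacts import (
    build_contact_map,
    classify_interaction,
    detect_ligand_contacts,
    diff_contact_maps,
)
from gpcreval.errors import ValidationError
from gpcreval.numbering import GenericPosition, NumberingMap
from gpcreval.structure_model import (
    Atom,
    ContactThresholds,
    LigandAtomChem,
    LigandDescriptor,
    Residue,
    StructureModel,
    VdwTable,
)
from tests.conftest import oracle_contact_map, oracle_ligand_contacts


def _atom(name, element, x, y, z, record_class="polymer"):
    return Atom(serial=1, name=name, element=element, coords=(x, y, z),
                record_class=record_class)


def _res(name3, atoms, seqnum=1, chain="A"):
    return Residue(chain=chain, seqnum=seqnum, icode="", name3=name3, atoms=atoms)


def _lig(atoms):
    return Residue(chain="L", seqnum=1, icode="", name3="LIG", atoms=atoms)


class TestClassifyInteraction:
    def test_ser_hydroxyl_donates_to_acceptor(self, thresholds):
        r = _res("SER", [_atom("CB", "C", 0, 0, 0), _atom("OG", "O", 0, 0, 1)])
        lig = _lig([_atom("O1", "O", 0, 0, 4.2, "hetero")])
        d = LigandDescriptor(atoms={"O1": LigandAtomChem(hb_acceptor=True)})
        assert classify_interaction(r, lig, d, thresholds) == {"hbond"}

    def test_asp_salt_bridge_to_cation(self, thresholds):
        r = _res("ASP", [_atom("OD1", "O", 0, 0, 0), _atom("OD2", "O", 1, 0, 0)])
        lig = _lig([_atom("N1", "N", 0, 0, 3.0, "hetero")])
        d = LigandDescriptor(atoms={"N1": LigandAtomChem(formal_charge=1)})
        assert classify_interaction(r, lig, d, thresholds) == {"salt_bridge"}

    def test_phe_ring_stacking_at_centroid_distance(self, thresholds):
        names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
        ring = [
            _atom(n, "C", 1.39 * np.cos(np.radians(60 * k)), 1.39 * np.sin(np.radians(60 * k)), 0)
            for k, n in enumerate(names)
        ]
        r = _res("PHE", ring)
        lig_ring = [
            _atom(f"C{k+1}", "C",
                  1.39 * np.cos(np.radians(60 * k)), 1.39 * np.sin(np.radians(60 * k)), 4.0,
                  "hetero")
            for k in range(6)
        ]
        lig = _lig(lig_ring)
        d = LigandDescriptor(atoms={f"C{k+1}": LigandAtomChem(ring_id=1) for k in range(6)})
        assert classify_interaction(r, lig, d, thresholds) == {"aromatic_stacking"}

    def test_leu_hydrophobic_but_backbone_polar_ignored(self, thresholds):
        # backbone N/O sit close to polar ligand atoms, yet only the
        # side-chain apolar contact counts
        r = _res("LEU", [
            _atom("N", "N", 0, 0, 3.0), _atom("O", "O", 0.5, 0, 3.0),
            _atom("CB", "C", 0, 0, 0), _atom("CD1", "C", 0, 0, 1.0),
        ])
        lig = _lig([
            _atom("O1", "O", 0, 0, 5.0, "hetero"),
            _atom("C7", "C", 0, 0, 5.2, "hetero"),
        ])
        d = LigandDescriptor(atoms={
            "O1": LigandAtomChem(hb_acceptor=True, hb_donor=True),
            "C7": LigandAtomChem(apolar_carbon=True),
        })
        assert classify_interaction(r, lig, d, thresholds) == {"hydrophobic"}

    def test_his_salt_bridge_only_when_protonated(self, thresholds):
        r = _res("HIS", [_atom("ND1", "N", 0, 0, 0), _atom("NE2", "N", 1, 0, 0)])
        lig = _lig([_atom("O2", "O", 0, 0, 3.5, "hetero")])
        d = LigandDescriptor(atoms={"O2": LigandAtomChem(formal_charge=-1)})
        assert "salt_bridge" not in classify_interaction(r, lig, d, thresholds)
        assert "salt_bridge" in classify_interaction(
            r, lig, d, thresholds, his_protonated=True
        )

    def test_no_interaction_is_empty_set(self, thresholds):
        r = _res("ALA", [_atom("CB", "C", 0, 0, 0)])
        lig = _lig([_atom("O1", "O", 0, 0, 5.0, "hetero")])
        d = LigandDescriptor(atoms={"O1": LigandAtomChem(hb_acceptor=True)})
        assert classify_interaction(r, lig, d, thresholds) == frozenset()


class TestDetectLigandContacts:
    def test_cutoff_is_strict(self, thresholds):
        lig = _lig([_atom("C7", "C", 0, 0, 0, "hetero")])
        d = LigandDescriptor(atoms={"C7": LigandAtomChem(apolar_carbon=True)})
        near = _res("ALA", [_atom("CB", "C", 0, 0, 5.4)], seqnum=1)
        at = _res("ALA", [_atom("CB", "C", 0, 0, 5.5)], seqnum=5)
        far = _res("ALA", [_atom("CB", "C", 0, 0, 5.6)], seqnum=9)
        s = StructureModel(id="t", residues=[near, at, far], ligands=[lig])
        got = {c.rid[1] for c in detect_ligand_contacts(s, lig, d, thresholds)}
        assert got == {1}

    def test_descriptor_must_cover_ligand_atoms(self, thresholds):
        lig = _lig([_atom("C7", "C", 0, 0, 0, "hetero"), _atom("C9", "C", 1, 0, 0, "hetero")])
        d = LigandDescriptor(atoms={"C7": LigandAtomChem(apolar_carbon=True)})
        s = StructureModel(id="t", residues=[_res("ALA", [_atom("CB", "C", 0, 0, 3)])],
                           ligands=[lig])
        with pytest.raises(ValidationError, match="C9"):
            detect_ligand_contacts(s, lig, d, thresholds)

    def test_planted_contacts_recovered_exactly(self, default_complex, thresholds):
        structure, descriptor, truth = default_complex
        contacts = detect_ligand_contacts(structure, structure.ligands[0], descriptor, thresholds)
        assert {c.rid[1] for c in contacts} == set(truth.planted)
        for c in contacts:
            assert c.labels == {truth.planted[c.rid[1]]}
            assert c.passes_chemical_filter

    def test_matches_distance_oracle(self, default_complex, thresholds):
        structure, descriptor, _ = default_complex
        lig = structure.ligands[0]
        got = {c.rid for c in detect_ligand_contacts(structure, lig, descriptor, thresholds)}
        assert got == oracle_ligand_contacts(structure, lig, thresholds.ligand_contact_cutoff)

    def test_rigid_transform_invariance(self, default_complex, thresholds):
        structure, descriptor, _ = default_complex
        rng = np.random.default_rng(7)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        shift = rng.uniform(-20, 20, 3)

        def move(res, record_class):
            return Residue(chain=res.chain, seqnum=res.seqnum, icode=res.icode,
                           name3=res.name3, atoms=[
                               Atom(serial=a.serial, name=a.name, element=a.element,
                                    coords=tuple(q @ np.asarray(a.coords) + shift),
                                    record_class=record_class)
                               for a in res.atoms])

        moved = StructureModel(
            id="moved",
            residues=[move(r, "polymer") for r in structure.residues],
            ligands=[move(l, "hetero") for l in structure.ligands],
        )
        before = [(c.rid, c.labels) for c in detect_ligand_contacts(
            structure, structure.ligands[0], descriptor, thresholds)]
        after = [(c.rid, c.labels) for c in detect_ligand_contacts(
            moved, moved.ligands[0], descriptor, thresholds)]
        assert before == after

    def test_raising_cutoffs_never_removes_contacts(self, default_complex):
        structure, descriptor, _ = default_complex
        lig = structure.ligands[0]
        tight = ContactThresholds()
        loose = ContactThresholds(ligand_contact_cutoff=7.0, hbond_max=4.0,
                                  salt_bridge_max=4.5, ring_centroid_max=5.5,
                                  hydrophobic_max=5.0)
        tight_set = {c.rid for c in detect_ligand_contacts(structure, lig, descriptor, tight)}
        loose_set = {c.rid for c in detect_ligand_contacts(structure, lig, descriptor, loose)}
        assert tight_set <= loose_set


class TestContactMap:
    def test_vdw_sum_rule_with_tolerance(self, vdw):
        a = _res("ALA", [_atom("CB", "C", 0, 0, 0)], seqnum=1)
        b = _res("ALA", [_atom("CB", "C", 3.2, 0, 0)], seqnum=10)
        s = StructureModel(id="t", residues=[a, b])
        cm = build_contact_map(s, vdw, ContactThresholds())  # cutoff 1.7+1.7+0.6=4.0
        assert (a.rid, b.rid) in cm

    def test_zero_tolerance_excludes_beyond_radius_sum(self, vdw):
        a = _res("ALA", [_atom("CB", "C", 0, 0, 0)], seqnum=1)
        b = _res("ALA", [_atom("CB", "C", 3.5, 0, 0)], seqnum=10)
        s = StructureModel(id="t", residues=[a, b])
        cm = build_contact_map(s, vdw, ContactThresholds(vdw_tolerance=0.0))
        assert len(cm) == 0

    def test_sequence_neighbours_excluded(self, vdw, thresholds):
        a = _res("ALA", [_atom("CB", "C", 0, 0, 0)], seqnum=1)
        b = _res("ALA", [_atom("CB", "C", 3.0, 0, 0)], seqnum=4)
        s = StructureModel(id="t", residues=[a, b])
        assert len(build_contact_map(s, vdw, thresholds)) == 0

    def test_glycine_participates_in_no_pairs(self, vdw, thresholds):
        gly = _res("GLY", [_atom("N", "N", 0, 0, 0), _atom("CA", "C", 1, 0, 0)], seqnum=1)
        b = _res("ALA", [_atom("CB", "C", 1.5, 0, 0)], seqnum=10)
        s = StructureModel(id="t", residues=[gly, b])
        assert len(build_contact_map(s, vdw, thresholds)) == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_bruteforce_oracle_on_state_pairs(self, seed, vdw, thresholds):
        from gpcreval.synthetic_data import gen_state_pair, sample_rewirable_pairs

        sp = gen_state_pair(seed, sample_rewirable_pairs(seed, 3))
        for structure in (sp.active, sp.inactive):
            cm = build_contact_map(structure, vdw, thresholds)
            assert set(cm.pairs) == oracle_contact_map(structure, vdw, thresholds)


class TestDiffContactMaps:
    @staticmethod
    def _maps():
        from gpcreval.contacts import ContactMap

        p = lambda i, j: frozenset((("A", i, ""), ("A", j, "")))
        cm_a = ContactMap(structure_id="a", pairs={p(1, 30): 3.0, p(2, 40): 3.1})
        cm_b = ContactMap(structure_id="b", pairs={p(1, 30): 3.0, p(3, 50): 3.2})
        nm = NumberingMap(pos_by_seqnum={
            1: GenericPosition(1, 41), 2: GenericPosition(1, 42), 3: GenericPosition(1, 43),
            30: GenericPosition(2, 46), 40: GenericPosition(2, 56), 50: GenericPosition(3, 43),
        })
        return cm_a, cm_b, nm

    def test_identical_maps_empty_diff(self):
        cm_a, _, nm = self._maps()
        gained, lost, dropped = diff_contact_maps(cm_a, cm_a, nm, nm)
        assert gained == set() and lost == set() and dropped == 0

    def test_swap_symmetry(self):
        cm_a, cm_b, nm = self._maps()
        g1, l1, _ = diff_contact_maps(cm_a, cm_b, nm, nm)
        g2, l2, _ = diff_contact_maps(cm_b, cm_a, nm, nm)
        assert g1 == l2 and l1 == g2

    def test_unmapped_pairs_dropped_and_counted(self):
        cm_a, cm_b, _ = self._maps()
        nm = NumberingMap(pos_by_seqnum={
            1: GenericPosition(1, 41), 30: GenericPosition(2, 46),
        })
        gained, lost, dropped = diff_contact_maps(cm_a, cm_b, nm, nm)
        assert gained == set() and lost == set()
        assert dropped == 2  # (2,40) in active, (3,50) in inactive

    def test_planted_rewiring_reported(self):
        from gpcreval.synthetic_data import gen_state_pair, synthetic_numbering

        pos = (GenericPosition(7, 52), GenericPosition(1, 53))
        sp = gen_state_pair(seed=2, rewired=[pos])
        nm = synthetic_numbering()
        cm_a = build_contact_map(sp.active)
        cm_i = build_contact_map(sp.inactive)
        gained, lost, _ = diff_contact_maps(cm_a, cm_i, nm, nm)
        assert gained == {frozenset(pos)}
        assert lost == set()
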