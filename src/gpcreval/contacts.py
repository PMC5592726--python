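"""Receptor-ligand contact detection and residue-residue contact maps.

Two distance criteria drive the package:

* a protein-ligand atomic contact exists when any heavy-atom pair is
  closer than 5.5 A, after which the contact must also realize at least
  one classical chemical interaction (hydrogen bond, salt bridge,
  aromatic stacking, or hydrophobic contact) to pass the chemical filter;
* a residue-residue contact exists when some side-chain heavy-atom pair
  is closer than the sum of the two van der Waals radii (plus a
  configurable tolerance), excluding backbone atoms and near-sequence
  neighbours.

The chemical-interaction rules are deterministic geometric replacements
for what is otherwise a visual-inspection step; every cutoff lives in
:class:`~gpcreval.structure_model.ContactThresholds`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gpcreval.errors import ValidationError
from gpcreval.numbering import GenericPosition, NumberingMap
from gpcreval.structure_model import (
    BACKBONE_ATOMS,
    Atom,
    ContactThresholds,
    LigandDescriptor,
    Residue,
    ResidueId,
    StructureModel,
    VdwTable,
    min_heavy_atom_distance,
)

# ---------------------------------------------------------------------------
# Side-chain chemistry templates (heavy-atom models; no explicit hydrogens)
# ---------------------------------------------------------------------------

#: Side-chain N/O hydrogen-bond donors per residue type.
SIDECHAIN_DONORS: dict[str, frozenset[str]] = {
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
    "ASN": frozenset({"ND2"}),
    "GLN": frozenset({"NE2"}),
    "LYS": frozenset({"NZ"}),
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "TRP": frozenset({"NE1"}),
    "HIS": frozenset({"ND1", "NE2"}),
}

#: Side-chain N/O hydrogen-bond acceptors per residue type.
SIDECHAIN_ACCEPTORS: dict[str, frozenset[str]] = {
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
    "ASN": frozenset({"OD1"}),
    "GLN": frozenset({"OE1"}),
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
    "HIS": frozenset({"ND1", "NE2"}),
}

#: Positively charged side-chain group atoms.  His contributes only when
#: explicitly flagged protonated.
POSITIVE_ATOMS: dict[str, frozenset[str]] = {
    "LYS": frozenset({"NZ"}),
    "ARG": frozenset({"NE", "NH1", "NH2"}),
}
HIS_POSITIVE_ATOMS = frozenset({"ND1", "NE2"})

#: Negatively charged side-chain group atoms.
NEGATIVE_ATOMS: dict[str, frozenset[str]] = {
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
}

#: Aromatic ring atoms used for centroid computation.
RING_ATOMS: dict[str, frozenset[str]] = {
    "PHE": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TYR": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TRP": frozenset({"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"}),
    "HIS": frozenset({"CG", "ND1", "CD2", "CE1", "NE2"}),
}

#: Apolar side-chain carbons: side-chain carbons not bonded to N or O in
#: the residue template.
APOLAR_CARBONS: dict[str, frozenset[str]] = {
    "ALA": frozenset({"CB"}),
    "VAL": frozenset({"CB", "CG1", "CG2"}),
    "LEU": frozenset({"CB", "CG", "CD1", "CD2"}),
    "ILE": frozenset({"CB", "CG1", "CG2", "CD1"}),
    "MET": frozenset({"CB", "CG", "CE"}),
    "PRO": frozenset({"CB", "CG"}),
    "PHE": frozenset({"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TYR": frozenset({"CB", "CG", "CD1", "CD2", "CE1", "CE2"}),
    "TRP": frozenset({"CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"}),
    "LYS": frozenset({"CB", "CG", "CD"}),
    "ARG": frozenset({"CB", "CG"}),
    "THR": frozenset({"CG2"}),
    "GLN": frozenset({"CB", "CG"}),
    "GLU": frozenset({"CB", "CG"}),
    "ASN": frozenset({"CB"}),
    "ASP": frozenset({"CB"}),
    "CYS": frozenset({"CB"}),
    "HIS": frozenset({"CB"}),
    "SER": frozenset(),
    "GLY": frozenset(),
}

INTERACTION_LABELS = ("hbond", "salt_bridge", "aromatic_stacking", "hydrophobic")


# ---------------------------------------------------------------------------
# Data types
# ---------------------------------------------------------------------------


@dataclass
class LigandContact:
    """One receptor residue in contact with the ligand."""

    rid: ResidueId
    resname: str
    min_distance: float
    labels: frozenset[str]
    generic_position: GenericPosition | None = None

    @property
    def passes_chemical_filter(self) -> bool:
        return bool(self.labels)


@dataclass
class ContactMap:
    """Unordered side-chain residue-pair contacts of one structure."""

    structure_id: str
    pairs: dict[frozenset, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair in self.pairs:
            if len(pair) != 2:
                raise ValidationError(f"contact pair must have two residues, got {set(pair)}")

    def __contains__(self, pair) -> bool:
        return frozenset(pair) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def to_tsv(self) -> str:
        lines = ["chain_i\tseqnum_i\tchain_j\tseqnum_j\tmin_sidechain_distance"]
        for pair in sorted(self.pairs, key=lambda p: sorted(p)):
            a, b = sorted(pair)
            lines.append(f"{a[0]}\t{a[1]}\t{b[0]}\t{b[1]}\t{self.pairs[pair]:.3f}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _atoms_by_name(res: Residue, names: frozenset[str]) -> list[Atom]:
    return [a for a in res.heavy_atoms if a.name in names]


def _min_dist(atoms_a: list[Atom], atoms_b: list[Atom]) -> float:
    if not atoms_a or not atoms_b:
        return float("inf")
    xa = np.array([a.coords for a in atoms_a], dtype=float)
    xb = np.array([b.coords for b in atoms_b], dtype=float)
    d2 = ((xa[:, None, :] - xb[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min()))


def _ligand_atoms(ligand: Residue, d: LigandDescriptor, predicate) -> list[Atom]:
    return [a for a in ligand.heavy_atoms if a.name in d.atoms and predicate(d.atoms[a.name])]


def _centroid(atoms: list[Atom]) -> np.ndarray:
    return np.array([a.coords for a in atoms], dtype=float).mean(axis=0)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def classify_interaction(
    r: Residue,
    ligand: Residue,
    d: LigandDescriptor,
    t: ContactThresholds,
    his_protonated: bool = False,
) -> frozenset[str]:
    """Classify the chemical interaction(s) a residue makes with the ligand.

    Returns a subset of ``{hbond, salt_bridge, aromatic_stacking,
    hydrophobic}``; an empty set means the residue fails the chemical
    filter.  Backbone polar atoms never contribute hydrogen bonds: the
    rules describe side-chain chemistry.
    """
    labels: set[str] = set()
    name3 = r.name3.upper()

    # hydrogen bond: residue side-chain donor/acceptor N or O within
    # hbond_max of a complementary ligand acceptor/donor
    res_donors = _atoms_by_name(r, SIDECHAIN_DONORS.get(name3, frozenset()))
    res_acceptors = _atoms_by_name(r, SIDECHAIN_ACCEPTORS.get(name3, frozenset()))
    lig_acceptors = _ligand_atoms(ligand, d, lambda i: i.hb_acceptor)
    lig_donors = _ligand_atoms(ligand, d, lambda i: i.hb_donor)
    if (
        _min_dist(res_donors, lig_acceptors) < t.hbond_max
        or _min_dist(res_acceptors, lig_donors) < t.hbond_max
    ):
        labels.add("hbond")

    # salt bridge: charged residue group atom within salt_bridge_max of an
    # oppositely charged ligand atom
    pos_names = POSITIVE_ATOMS.get(name3, frozenset())
    if name3 == "HIS" and his_protonated:
        pos_names = pos_names | HIS_POSITIVE_ATOMS
    res_pos = _atoms_by_name(r, pos_names)
    res_neg = _atoms_by_name(r, NEGATIVE_ATOMS.get(name3, frozenset()))
    lig_pos = _ligand_atoms(ligand, d, lambda i: i.formal_charge > 0)
    lig_neg = _ligand_atoms(ligand, d, lambda i: i.formal_charge < 0)
    if (
        _min_dist(res_pos, lig_neg) < t.salt_bridge_max
        or _min_dist(res_neg, lig_pos) < t.salt_bridge_max
    ):
        labels.add("salt_bridge")

    # aromatic stacking: ring-centroid distance below ring_centroid_max
    ring_names = RING_ATOMS.get(name3)
    if ring_names:
        res_ring = _atoms_by_name(r, ring_names)
        if len(res_ring) >= 3:
            rc = _centroid(res_ring)
            for atom_names in d.ring_groups().values():
                lig_ring = [a for a in ligand.heavy_atoms if a.name in atom_names]
                if len(lig_ring) >= 3:
                    lc = _centroid(lig_ring)
                    if float(np.linalg.norm(rc - lc)) < t.ring_centroid_max:
                        labels.add("aromatic_stacking")
                        break

    # hydrophobic: apolar residue carbon near an apolar ligand carbon
    res_apolar = _atoms_by_name(r, APOLAR_CARBONS.get(name3, frozenset()))
    lig_apolar = _ligand_atoms(ligand, d, lambda i: i.apolar_carbon)
    if _min_dist(res_apolar, lig_apolar) < t.hydrophobic_max:
        labels.add("hydrophobic")

    return frozenset(labels)


def detect_ligand_contacts(
    s: StructureModel,
    ligand: Residue,
    d: LigandDescriptor,
    t: ContactThresholds | None = None,
    numbering: NumberingMap | None = None,
    his_protonated: bool = False,
) -> list[LigandContact]:
    """All polymer residues within the ligand-contact cutoff, with labels.

    One record per residue whose minimum heavy-atom distance to any
    ligand atom is strictly below ``t.ligand_contact_cutoff``, ordered by
    (chain, seqnum, icode).  Each record carries the chemical-interaction
    labels from :func:`classify_interaction`.
    """
    t = t or ContactThresholds()
    d.validate_against(ligand)
    out: list[LigandContact] = []
    for res in s.residues:
        if not res.heavy_atoms:
            continue
        dist = min_heavy_atom_distance(res, ligand, atom_filter="all")
        if dist < t.ligand_contact_cutoff:
            labels = classify_interaction(res, ligand, d, t, his_protonated=his_protonated)
            gp = numbering.position_of(res.seqnum) if numbering is not None else None
            out.append(
                LigandContact(
                    rid=res.rid,
                    resname=res.name3,
                    min_distance=dist,
                    labels=labels,
                    generic_position=gp,
                )
            )
    out.sort(key=lambda c: c.rid)
    return out


def build_contact_map(
    s: StructureModel,
    vdw: VdwTable | None = None,
    t: ContactThresholds | None = None,
) -> ContactMap:
    """Side-chain residue-residue contact map under the vdW-sum rule.

    A pair (i, j) is included iff some side-chain heavy-atom pair lies
    closer than ``r_vdw(a) + r_vdw(b) + t.vdw_tolerance`` and the two
    residues are separated by at least ``t.min_seq_separation`` in
    sequence (same chain).  Glycine has no side chain and participates in
    no pairs.
    """
    vdw = vdw or VdwTable()
    t = t or ContactThresholds()
    entries = []
    for res in s.residues:
        sc = [a for a in res.heavy_atoms if a.name not in BACKBONE_ATOMS]
        if sc:
            coords = np.array([a.coords for a in sc], dtype=float)
            radii = np.array([vdw.radius(a) for a in sc], dtype=float)
            entries.append((res, coords, radii))
    pairs: dict[frozenset, float] = {}
    for i in range(len(entries)):
        ri, ci, radi = entries[i]
        for j in range(i + 1, len(entries)):
            rj, cj, radj = entries[j]
            if ri.chain == rj.chain and abs(ri.seqnum - rj.seqnum) < t.min_seq_separation:
                continue
            dmat = np.sqrt(((ci[:, None, :] - cj[None, :, :]) ** 2).sum(axis=2))
            cut = radi[:, None] + radj[None, :] + t.vdw_tolerance
            if (dmat < cut).any():
                pairs[frozenset((ri.rid, rj.rid))] = float(dmat.min())
    return ContactMap(structure_id=s.id, pairs=pairs)


def diff_contact_maps(
    active: ContactMap,
    inactive: ContactMap,
    na: NumberingMap,
    ni: NumberingMap,
) -> tuple[set[frozenset], set[frozenset], int]:
    """Contact-map difference in generic-position space.

    Returns ``(gained, lost, n_dropped)``: pairs present only in the
    active map, pairs present only in the inactive map, and the number of
    pairs dropped because one residue had no generic number.  Swapping
    the arguments swaps gained and lost.
    """

    def to_generic(cm: ContactMap, nm: NumberingMap) -> tuple[set[frozenset], int]:
        out: set[frozenset] = set()
        dropped = 0
        for pair in cm.pairs:
            a, b = tuple(pair)
            ga, gb = nm.position_of(a[1]), nm.position_of(b[1])
            if ga is None or gb is None:
                dropped += 1
                continue
            out.add(frozenset((ga, gb)))
        return out, dropped

    set_a, drop_a = to_generic(active, na)
    set_i, drop_i = to_generic(inactive, ni)
    return set_a - set_i, set_i - set_a, drop_a + drop_i


def contacts_to_tsv(contacts: list[LigandContact]) -> str:
    lines = ["chain\tseqnum\ticode\tresname\tgeneric_position\tmin_distance\tlabels\tpasses_filter"]
    for c in contacts:
        gp = str(c.generic_position) if c.generic_position else "-"
        labels = ",".join(sorted(c.labels)) if c.labels else "-"
        lines.append(
            f"{c.rid[0]}\t{c.rid[1]}\t{c.rid[2] or '-'}\t{c.resname}\t{gp}\t"
            f"{c.min_distance:.3f}\t{labels}\t{int(c.passes_chemical_filter)}"
        )
    return "\n".join(lines) + "\n"


__all__ = [
    "LigandContact",
    "ContactMap",
    "classify_interaction",
    "detect_ligand_contacts",
    "build_contact_map",
    "diff_contact_maps",
    "contacts_to_tsv",
    "SIDECHAIN_DONORS",
    "SIDECHAIN_ACCEPTORS",
    "POSITIVE_ATOMS",
    "NEGATIVE_ATOMS",
    "RING_ATOMS",
    "APOLAR_CARBONS",
    "INTERACTION_LABELS",
]
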