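"""Seeded generators for every input the pipeline consumes.

The generators emit idealized seven-helix bundles with a bound ligand,
mutagenesis tables, family alignments and active/inactive state pairs --
all with planted ground truth, so every downstream stage can be tested
end-to-end without external data.  Geometry is deliberately schematic
(helical Calpha traces, 1-3 pseudo-atom side chains with correct element
types): the goal is that every distance and chemistry rule engages
exactly as planted, not physical realism.  Planted interactions sit
0.3 A inside their cutoff and decoys at least 0.5 A outside the
ligand-contact cutoff, margins that dominate the 1e-3 A coordinate
round-off of the PDB format.  Every generator is a pure function of
(seed, parameters), and each verifies its own planted margins by brute
force before returning -- a request it cannot realize fails loudly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from gpcreval.contacts import classify_interaction
from gpcreval.errors import GenerationError, ValidationError
from gpcreval.binding_eval import MutagenesisRecord
from gpcreval.conservation import AlignedFamily
from gpcreval.numbering import (
    GenericPosition,
    NumberingMap,
    ReferenceAnnotation,
    assign_generic_numbers,
)
from gpcreval.structure_model import (
    Atom,
    ContactThresholds,
    LigandAtomChem,
    LigandDescriptor,
    Residue,
    StructureModel,
    write_pdb,
)

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}


# ---------------------------------------------------------------------------
# Geometry and template
# ---------------------------------------------------------------------------


@dataclass
class BundleGeometry:
    """Idealized seven-helix bundle parameters (A / degrees)."""

    residues_per_helix: int = 24
    rise: float = 1.5
    turn_deg: float = 100.0
    helix_radius: float = 2.3
    bundle_radius: float = 12.0
    ligand_z: float = 7.0

    @property
    def n_residues(self) -> int:
        return 7 * self.residues_per_helix

    @property
    def z_top(self) -> float:
        return (self.residues_per_helix - 1) * self.rise / 2.0


#: Conserved bitter-taste-receptor-style positions planted in the
#: synthetic template sequence (everything else is Leu background).
_TEMPLATE_SPECIAL = {
    (1, 50): "N", (1, 53): "I",
    (2, 46): "L", (2, 50): "R",
    (3, 46): "L", (3, 49): "F", (3, 50): "Y", (3, 53): "K",
    (5, 42): "S", (5, 43): "L", (5, 50): "P",
    (6, 44): "F", (6, 48): "Y",
    (7, 49): "H", (7, 50): "S", (7, 52): "I", (7, 53): "L",
}


def synthetic_template(residues_per_helix: int = 24) -> str:
    """Template sequence of the synthetic bundle: 7 contiguous TM helices."""
    anchor = residues_per_helix // 2
    seq = []
    for h in range(1, 8):
        for i in range(residues_per_helix):
            offset = 50 + (i - anchor)
            seq.append(_TEMPLATE_SPECIAL.get((h, offset), "L"))
    return "".join(seq)


def synthetic_annotation(residues_per_helix: int = 24) -> ReferenceAnnotation:
    """Reference annotation matching :func:`synthetic_template`."""
    anchor = residues_per_helix // 2
    spans = {}
    anchors = {}
    for h in range(1, 8):
        start = (h - 1) * residues_per_helix
        spans[h] = (start, start + residues_per_helix)
        anchors[h] = start + anchor
    return ReferenceAnnotation(
        template_id="synth7tm",
        template_seq=synthetic_template(residues_per_helix),
        tm_spans=spans,
        anchors=anchors,
    )


def synthetic_numbering(residues_per_helix: int = 24) -> NumberingMap:
    """Seqnum <-> generic-position map of the synthetic bundle (seqnums 1..N)."""
    ann = synthetic_annotation(residues_per_helix)
    return assign_generic_numbers(ann.template_seq, ann.template_seq, ann)


def _helix_azimuth(h: int) -> float:
    return 2.0 * math.pi * (h - 1) / 7.0


def _u(h: int) -> np.ndarray:
    th = _helix_azimuth(h)
    return np.array([math.cos(th), math.sin(th), 0.0])


def _ca_position(h: int, i: int, g: BundleGeometry) -> np.ndarray:
    """Calpha of residue i (0-based) of helix h; odd helices run top-down."""
    th = _helix_azimuth(h)
    cx, cy = g.bundle_radius * math.cos(th), g.bundle_radius * math.sin(th)
    z = g.z_top - i * g.rise if h % 2 == 1 else -g.z_top + i * g.rise
    phi = th + math.radians(g.turn_deg) * i
    return np.array(
        [cx + g.helix_radius * math.cos(phi), cy + g.helix_radius * math.sin(phi), z]
    )


def _radial_out(p: np.ndarray) -> np.ndarray:
    v = np.array([p[0], p[1], 0.0])
    n = np.linalg.norm(v)
    return v / n if n > 1e-9 else np.array([1.0, 0.0, 0.0])


_BB_N = np.array([1.33, 0.00, 0.48])
_BB_C = np.array([-0.53, 1.25, -0.45])
_BB_O = np.array([-0.53, 1.25, -1.68])


def _round3(v: np.ndarray) -> tuple[float, float, float]:
    # bake PDB precision into the in-memory model so parse/write round-trips
    return (round(float(v[0]), 3), round(float(v[1]), 3), round(float(v[2]), 3))


def _make_residue(
    h: int, i: int, seqnum: int, name3: str, g: BundleGeometry,
    sidechain: list[tuple[str, str, np.ndarray]] | None = None,
) -> Residue:
    """Backbone (N, CA, C, O) plus either a default outward CB stub or the
    supplied side-chain pseudo-atoms."""
    ca = _ca_position(h, i, g)
    atoms = [
        Atom(serial=0, name="N", element="N", coords=_round3(ca + _BB_N)),
        Atom(serial=0, name="CA", element="C", coords=_round3(ca)),
        Atom(serial=0, name="C", element="C", coords=_round3(ca + _BB_C)),
        Atom(serial=0, name="O", element="O", coords=_round3(ca + _BB_O)),
    ]
    if sidechain is None:
        if name3 != "GLY":
            cb = ca + 1.53 * _radial_out(ca)
            atoms.append(Atom(serial=0, name="CB", element="C", coords=_round3(cb)))
    else:
        for name, element, pos in sidechain:
            atoms.append(Atom(serial=0, name=name, element=element, coords=_round3(pos)))
    return Residue(chain="A", seqnum=seqnum, icode="", name3=name3, atoms=atoms)


def _renumber_serials(residues: list[Residue], ligands: list[Residue]) -> None:
    serial = 0
    for res in list(residues) + list(ligands):
        new_atoms = []
        for a in res.atoms:
            serial += 1
            new_atoms.append(
                Atom(serial=serial, name=a.name, element=a.element, coords=a.coords,
                     occupancy=a.occupancy, altloc=a.altloc, record_class=a.record_class)
            )
        res.atoms = new_atoms


# ---------------------------------------------------------------------------
# Ground-truth records
# ---------------------------------------------------------------------------


@dataclass
class ComplexTruth:
    """Planted ground truth of a generated receptor-ligand complex."""

    planted: dict[int, str]            # seqnum -> intended interaction label
    decoys: list[int]                  # seqnums >= 0.5 A outside the contact cutoff
    top_half: dict[int, bool]          # seqnum -> Calpha in the extracellular half
    residue_names: dict[int, str]      # seqnum -> three-letter code
    ligand_chain: str = "L"
    ligand_seqnum: int = 1


@dataclass
class ScenarioTruth:
    """Intended confusion matrix and the table realizing it."""

    intended: tuple[int, int, int, int]  # (TP, FP, TN, FN)
    records: list[MutagenesisRecord] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Receptor-ligand complex generator
# ---------------------------------------------------------------------------

#: Helix visiting order that keeps consecutive interaction slots far apart
#: in azimuth, so each planted side chain only sees its own ligand atom.
_HELIX_SPREAD = [1, 4, 7, 3, 6, 2, 5]

#: Default ligand-atom direction per label when that label is not planted.
_DEFAULT_LABEL_HELIX = {"hbond": 1, "salt_bridge": 4, "aromatic_stacking": 7, "hydrophobic": 3}

_LABEL_ORDER = ("hbond", "salt_bridge", "aromatic_stacking", "hydrophobic")


def _perp_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    z = np.array([0.0, 0.0, 1.0])
    p = np.cross(d, z)
    if np.linalg.norm(p) < 1e-6:
        p = np.cross(d, np.array([1.0, 0.0, 0.0]))
    p = p / np.linalg.norm(p)
    q = np.cross(d, p)
    return p, q / np.linalg.norm(q)


def _hexagon(center: np.ndarray, p: np.ndarray, q: np.ndarray, radius: float = 1.39) -> list[np.ndarray]:
    return [
        center + radius * (math.cos(math.radians(60 * k)) * p + math.sin(math.radians(60 * k)) * q)
        for k in range(6)
    ]


def gen_bundle_complex(
    seed: int,
    n_contacts_per_label: dict[str, int] | None = None,
    n_decoys: int = 3,
    geometry: BundleGeometry | None = None,
    thresholds: ContactThresholds | None = None,
) -> tuple[str, LigandDescriptor, ComplexTruth]:
    """Seven-helix bundle with a centrally bound ligand and planted contacts.

    Each planted residue realizes exactly one interaction rule 0.3 A
    inside its cutoff; decoy residues sit at least 0.5 A outside the
    ligand-contact cutoff.  Returns ``(pdb_text, descriptor, truth)``;
    identical seeds give byte-identical PDB text.
    """
    g = geometry or BundleGeometry()
    t = thresholds or ContactThresholds()
    labels_requested = dict(n_contacts_per_label or {})
    for lab, n in labels_requested.items():
        if lab not in _LABEL_ORDER:
            raise ValidationError(f"unknown interaction label {lab!r}")
        if n < 0:
            raise ValidationError(f"negative count for label {lab!r}")
    slots = [lab for lab in _LABEL_ORDER for _ in range(labels_requested.get(lab, 0))]
    if len(slots) > 7:
        raise GenerationError(f"cannot plant {len(slots)} contacts on 7 helices")
    if labels_requested.get("aromatic_stacking", 0) > 1:
        # the ligand carries a single ring; a second stacking partner would
        # have to reach across the bundle axis and sweep the apolar carbons
        raise GenerationError("at most one aromatic_stacking contact can be planted")
    rng = np.random.default_rng(seed)

    rph = g.residues_per_helix
    # slot k (label slots[k]) -> helix _HELIX_SPREAD[k]
    slot_helices = [_HELIX_SPREAD[k] for k in range(len(slots))]

    # direction of each label's ligand atom: azimuth of its first slot; an
    # unplanted label points at a helix no slot uses, so its atom never sits
    # in front of a planted side chain
    spare = [h for h in _HELIX_SPREAD if h not in set(slot_helices)]
    label_dir_helix: dict[str, int] = {}
    for lab in _LABEL_ORDER:
        if lab in slots:
            label_dir_helix[lab] = slot_helices[slots.index(lab)]
        elif spare:
            label_dir_helix[lab] = spare.pop()
        else:
            label_dir_helix[lab] = _DEFAULT_LABEL_HELIX[lab]

    center = np.array([0.0, 0.0, g.ligand_z])
    u_hb = _u(label_dir_helix["hbond"])
    u_salt = _u(label_dir_helix["salt_bridge"])
    u_ar = _u(label_dir_helix["aromatic_stacking"])
    u_hy = _u(label_dir_helix["hydrophobic"])

    # host residue per slot: the residue of the slot's helix whose Calpha z is
    # nearest the ligand, with a small seeded up/down shift
    hosts: dict[int, tuple[str, int]] = {}  # seqnum -> (label, helix)
    host_of_slot: list[int] = []
    for k, lab in enumerate(slots):
        h = slot_helices[k]
        best_i = min(range(rph), key=lambda i: abs(_ca_position(h, i, g)[2] - g.ligand_z))
        i = int(np.clip(best_i + rng.integers(-1, 2), 1, rph - 2))
        seqnum = (h - 1) * rph + i + 1
        if seqnum in hosts:
            raise GenerationError(f"host residue collision at seqnum {seqnum}")
        hosts[seqnum] = (lab, h)
        host_of_slot.append(seqnum)

    # --- ligand -----------------------------------------------------------
    lig_positions: dict[str, np.ndarray] = {
        "N1": center.copy(),
        "O1": center + 1.4 * u_hb + np.array([0.0, 0.0, 0.5]),
        # apolar carbons stay near the bundle axis so planted aromatic rings
        # (whose carbons are genuinely apolar) never drift into their
        # hydrophobic-contact range
        "C7": center + 0.4 * u_hy + np.array([0.0, 0.0, 0.9]),
        "C8": center + 0.3 * u_hy + np.array([0.0, 0.0, -0.8]),
    }
    ring_center = center + 0.8 * u_ar - np.array([0.0, 0.0, 1.2])
    # orient the ring face toward the aromatic host's Calpha
    if "aromatic_stacking" in slots:
        k = slots.index("aromatic_stacking")
        h, sn = slot_helices[k], host_of_slot[k]
        d_ar = _ca_position(h, (sn - 1) % rph, g) - ring_center
    else:
        d_ar = _u(label_dir_helix["aromatic_stacking"])
    d_ar = d_ar / np.linalg.norm(d_ar)
    p_ar, q_ar = _perp_basis(d_ar)
    for k, pos in enumerate(_hexagon(ring_center, p_ar, q_ar)):
        lig_positions[f"C{k + 1}"] = pos

    lig_atoms = []
    lig_order = ["N1", "O1", "C1", "C2", "C3", "C4", "C5", "C6", "C7", "C8"]
    for name in lig_order:
        el = "N" if name.startswith("N") else ("O" if name.startswith("O") else "C")
        lig_atoms.append(Atom(serial=0, name=name, element=el,
                              coords=_round3(lig_positions[name]), record_class="hetero"))
    ligand = Residue(chain="L", seqnum=1, icode="", name3="LIG", atoms=lig_atoms)

    descriptor = LigandDescriptor(
        atoms={
            "N1": LigandAtomChem(formal_charge=1),
            # acceptor-only (ether-like): planted hydrogen bonds are always
            # residue-donor -> ligand-acceptor, so acidic side chains near the
            # ligand can never pick up a second, unplanted hbond label
            "O1": LigandAtomChem(hb_acceptor=True),
            **{f"C{k}": LigandAtomChem(ring_id=1) for k in range(1, 7)},
            "C7": LigandAtomChem(apolar_carbon=True),
            "C8": LigandAtomChem(apolar_carbon=True),
        }
    )

    # --- receptor ---------------------------------------------------------
    residues: list[Residue] = []
    truth_names: dict[int, str] = {}
    planted: dict[int, str] = {}
    for h in range(1, 8):
        for i in range(rph):
            seqnum = (h - 1) * rph + i + 1
            if seqnum in hosts:
                lab = hosts[seqnum][0]
                res = _planted_residue(h, i, seqnum, lab, lig_positions, ring_center, g, t)
                planted[seqnum] = lab
            else:
                res = _make_residue(h, i, seqnum, "LEU", g)
            residues.append(res)
            truth_names[seqnum] = res.name3

    top_half = {r.seqnum: bool(r.ca.xyz[2] >= 0.0) for r in residues}

    # --- decoys -----------------------------------------------------------
    candidates = [r.seqnum for r in residues
                  if top_half[r.seqnum] and r.seqnum not in planted]
    if n_decoys > len(candidates):
        raise GenerationError(f"cannot pick {n_decoys} decoys from {len(candidates)} candidates")
    decoys = sorted(rng.choice(candidates, size=n_decoys, replace=False).tolist()) if n_decoys else []

    _renumber_serials(residues, [ligand])
    structure = StructureModel(id=f"synth-complex-{seed}", residues=residues, ligands=[ligand])
    truth = ComplexTruth(planted=planted, decoys=decoys, top_half=top_half,
                         residue_names=truth_names)
    _verify_complex(structure, ligand, descriptor, truth, t)
    return write_pdb(structure), descriptor, truth


def _chain_positions(ca: np.ndarray, target: np.ndarray, dist: float, n_atoms: int):
    """Pseudo side chain from near the Calpha to ``dist`` short of the target."""
    d = target - ca
    d = d / np.linalg.norm(d)
    tip = target - dist * d
    first = ca + 1.53 * d
    if n_atoms == 1:
        return [tip], d
    step = (tip - first) / (n_atoms - 1)
    return [first + k * step for k in range(n_atoms)], d


def _planted_residue(h, i, seqnum, label, lig_positions, ring_center,
                     g: BundleGeometry, t: ContactThresholds) -> Residue:
    ca = _ca_position(h, i, g)
    if label == "hbond":
        chain, _ = _chain_positions(ca, lig_positions["O1"], t.hbond_max - 0.3, 2)
        sc = [("CB", "C", chain[0]), ("OG", "O", chain[1])]
        return _make_residue(h, i, seqnum, "SER", g, sidechain=sc)
    if label == "salt_bridge":
        chain, d = _chain_positions(ca, lig_positions["N1"], t.salt_bridge_max - 0.3, 3)
        perp, _ = _perp_basis(d)
        od2 = chain[2] - 0.6 * d + 1.1 * perp
        sc = [("CB", "C", chain[0]), ("CG", "C", chain[1]),
              ("OD1", "O", chain[2]), ("OD2", "O", od2)]
        return _make_residue(h, i, seqnum, "ASP", g, sidechain=sc)
    if label == "hydrophobic":
        chain, _ = _chain_positions(ca, lig_positions["C7"], t.hydrophobic_max - 0.3, 3)
        sc = [("CB", "C", chain[0]), ("CG", "C", chain[1]), ("CD1", "C", chain[2])]
        return _make_residue(h, i, seqnum, "LEU", g, sidechain=sc)
    if label == "aromatic_stacking":
        # face this host's own Calpha so multiple stacking slots never overlap
        d = ca - ring_center
        d = d / np.linalg.norm(d)
        p, q = _perp_basis(d)
        ring_g = ring_center + (t.ring_centroid_max - 0.3) * d
        ring = _hexagon(ring_g, p, q)
        names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
        sc = [(n, "C", p) for n, p in zip(names, ring)]
        to_ca = ca - ring_g
        to_ca = to_ca / np.linalg.norm(to_ca)
        cb = ring[0] + 1.5 * to_ca
        sc.append(("CB", "C", cb))
        return _make_residue(h, i, seqnum, "PHE", g, sidechain=sc)
    raise ValidationError(f"unknown label {label!r}")


def _verify_complex(structure: StructureModel, ligand: Residue,
                    descriptor: LigandDescriptor, truth: ComplexTruth,
                    t: ContactThresholds) -> None:
    """Brute-force margin check of the emitted coordinates; fails loudly."""
    lig_xyz = [np.asarray(a.coords) for a in ligand.heavy_atoms]
    for res in structure.residues:
        dmin = min(
            float(np.linalg.norm(np.asarray(a.coords) - lx))
            for a in res.heavy_atoms for lx in lig_xyz
        )
        if res.seqnum in truth.planted:
            if dmin >= t.ligand_contact_cutoff - 0.3:
                raise GenerationError(
                    f"planted residue {res.seqnum} at {dmin:.2f} A violates the contact margin"
                )
            got = classify_interaction(res, ligand, descriptor, t)
            want = frozenset({truth.planted[res.seqnum]})
            if got != want:
                raise GenerationError(
                    f"planted residue {res.seqnum}: labels {set(got)} != planted {set(want)}"
                )
        else:
            if dmin < t.ligand_contact_cutoff + 0.5:
                raise GenerationError(
                    f"non-planted residue {res.seqnum} at {dmin:.2f} A violates the decoy margin"
                )


# ---------------------------------------------------------------------------
# Mutagenesis table generator
# ---------------------------------------------------------------------------


def gen_mutagenesis_table(
    truth: ComplexTruth,
    intended: tuple[int, int, int, int],
    seed: int,
    receptor: str = "synthR",
) -> tuple[list[MutagenesisRecord], ScenarioTruth]:
    """Mutagenesis table realizing an intended (TP, FP, TN, FN) against
    the planted complex truth.

    Affecting mutations go to TP planted-contact residues and FN
    non-contact residues; no-effect mutations to FP planted-contact
    residues and TN non-contact residues.  All chosen residues lie in the
    top half.  An unrealizable request raises.
    """
    tp, fp, tn, fn = intended
    if min(intended) < 0:
        raise ValidationError("intended counts must be non-negative")
    rng = np.random.default_rng(seed)
    contact_pool = [sn for sn in sorted(truth.planted) if truth.top_half[sn]]
    noncontact_pool = list(truth.decoys)
    if tp + fp > len(contact_pool):
        raise GenerationError(
            f"need {tp + fp} tested contact residues but only {len(contact_pool)} planted"
        )
    if tn + fn > len(noncontact_pool):
        raise GenerationError(
            f"need {tn + fn} tested non-contact residues but only {len(noncontact_pool)} decoys"
        )
    contact_pick = rng.permutation(contact_pool)[: tp + fp]
    noncontact_pick = rng.permutation(noncontact_pool)[: tn + fn]

    nmap = synthetic_numbering()
    records: list[MutagenesisRecord] = []

    def _record(seqnum: int, affects: bool) -> MutagenesisRecord:
        aa1 = AA3_TO_1.get(truth.residue_names[seqnum], "X")
        to = "A" if aa1 != "A" else "G"
        fold = float(rng.uniform(5.0, 50.0)) if affects else float(rng.uniform(1.0, 1.5))
        return MutagenesisRecord(
            receptor=receptor,
            seqnum=seqnum,
            generic_position=nmap.position_of(seqnum),
            mutation=f"{aa1}{seqnum}{to}",
            effect_class="affects_response" if affects else "no_effect",
            ec50_fold_change=round(fold, 2),
            source="synthetic",
        )

    for sn in contact_pick[:tp]:
        records.append(_record(int(sn), True))
    for sn in contact_pick[tp:]:
        records.append(_record(int(sn), False))
    for sn in noncontact_pick[:fn]:
        records.append(_record(int(sn), True))
    for sn in noncontact_pick[fn:]:
        records.append(_record(int(sn), False))
    records.sort(key=lambda r: r.seqnum)
    return records, ScenarioTruth(intended=intended, records=records)


# ---------------------------------------------------------------------------
# Family MSA generator
# ---------------------------------------------------------------------------


def gen_family_msa(
    seed: int,
    n_rows: int,
    profiles: dict[GenericPosition, list[tuple[str, float]]] | None = None,
    n_gap_defective: int = 0,
    gap_fraction: float = 0.4,
    n_motif_defective: int = 0,
    motif_defect_positions: list[GenericPosition] | None = None,
    residues_per_helix: int = 24,
) -> AlignedFamily:
    """Family alignment with exact planted per-column residue frequencies.

    ``profiles`` maps a generic position to ``[(residue, frequency), ...]``;
    realized counts are ``round(frequency * n_rows)`` exactly, with the
    assignment to rows shuffled by the seed.  Row 0 is the reference row
    and always carries the template sequence.  Gap-defective rows
    (``gapdefNNNN``) receive gaps in ``gap_fraction`` of the TM columns;
    motif-defective rows (``motifdefNNNN``) receive gaps at the
    ``motif_defect_positions`` (default: the five X.50 anchors of TM
    helices 1, 2, 3, 5 and 7), so they fail conserved-feature scans while
    staying under typical gap-fraction thresholds.
    """
    if n_rows < 1:
        raise ValidationError("n_rows must be >= 1")
    profiles = profiles or {}
    ann = synthetic_annotation(residues_per_helix)
    template = ann.template_seq
    width = len(template)
    rng = np.random.default_rng(seed)

    n_plain = n_rows - 1 - n_gap_defective - n_motif_defective
    if n_plain < 0:
        raise ValidationError("defective rows exceed n_rows - 1 (row 0 is the reference)")

    ids = ["ref"]
    ids += [f"seq{i:04d}" for i in range(n_plain)]
    ids += [f"gapdef{i:04d}" for i in range(n_gap_defective)]
    ids += [f"motifdef{i:04d}" for i in range(n_motif_defective)]
    grid = [list(template) for _ in range(n_rows)]

    nmap = synthetic_numbering(residues_per_helix)
    profile_cols: dict[int, list[tuple[str, float]]] = {}
    for pos, entries in profiles.items():
        sn = nmap.residue_at(pos)
        if sn is None:
            raise ValidationError(f"profiled position {pos} outside the synthetic TM spans")
        col = sn - 1
        total = 0
        for res, freq in entries:
            if not 0.0 <= freq <= 1.0:
                raise ValidationError(f"frequency {freq} for {res} at {pos} outside [0,1]")
            total += int(math.floor(freq * n_rows + 0.5))
        if total > n_rows:
            raise ValidationError(f"profile at {pos} allocates {total} > {n_rows} rows")
        profile_cols[col] = [(r.upper(), f) for r, f in entries]

    for col, entries in profile_cols.items():
        tchar = template[col]
        profiled_res = {r for r, _ in entries}
        # filler for unassigned rows must not collide with a profiled residue
        filler = tchar
        if tchar in profiled_res:
            filler = next(c for c in "AGSTVMLIFWYQNEDKRHPC" if c not in profiled_res)
        order = [0] + [int(r) + 1 for r in rng.permutation(n_rows - 1)]
        assigned: dict[int, str] = {}
        for res, freq in entries:
            k = int(math.floor(freq * n_rows + 0.5))
            if k == 0:
                continue
            if res == tchar:
                assigned[0] = res
                k -= 1
            pool = [r for r in order if r != 0 and r not in assigned]
            if k > len(pool):
                raise ValidationError(f"profile at column {col} is over-allocated")
            for r in pool[:k]:
                assigned[r] = res
        for r in range(n_rows):
            grid[r][col] = assigned.get(r, tchar if r == 0 else filler)

    tm_cols = sorted(set(range(width)))  # the whole synthetic template is TM
    free_cols = [c for c in tm_cols if c not in profile_cols]

    defect_positions = (
        motif_defect_positions or [GenericPosition(h, 50) for h in (1, 2, 3, 5, 7)]
        if n_motif_defective
        else []
    )
    defect_cols = []
    for pos in defect_positions:
        sn = nmap.residue_at(pos)
        if sn is None:
            raise ValidationError(f"motif defect position {pos} outside the TM spans")
        if (sn - 1) in profile_cols:
            raise ValidationError(f"motif defect position {pos} collides with a profile")
        defect_cols.append(sn - 1)

    n_gap_cols = int(round(gap_fraction * len(tm_cols)))
    gap_eligible = [c for c in free_cols if c not in defect_cols]
    if n_gap_defective and n_gap_cols > len(gap_eligible):
        raise ValidationError("gap_fraction too high for the available non-profiled columns")
    row_offset = 1 + n_plain
    for k in range(n_gap_defective):
        cols = rng.choice(gap_eligible, size=n_gap_cols, replace=False)
        for c in cols:
            grid[row_offset + k][int(c)] = "-"
    row_offset += n_gap_defective
    for k in range(n_motif_defective):
        for c in defect_cols:
            grid[row_offset + k][c] = "-"

    rows = [(rid, "".join(g)) for rid, g in zip(ids, grid)]
    fam = AlignedFamily.from_alignment(rows, "ref", ann)
    # verify planted counts exactly
    for col, entries in profile_cols.items():
        for res, freq in entries:
            want = int(math.floor(freq * n_rows + 0.5))
            got = sum(1 for _, seq in rows if seq[col] == res)
            if got != want:
                raise GenerationError(f"column {col}: planted {want} x {res}, realized {got}")
    return fam


# ---------------------------------------------------------------------------
# Active/inactive state pair generator
# ---------------------------------------------------------------------------


def _bare_bundle(g: BundleGeometry, structure_id: str, state_label: str) -> StructureModel:
    residues = []
    for h in range(1, 8):
        for i in range(g.residues_per_helix):
            seqnum = (h - 1) * g.residues_per_helix + i + 1
            residues.append(_make_residue(h, i, seqnum, "LEU", g))
    _renumber_serials(residues, [])
    return StructureModel(id=structure_id, residues=residues, state_label=state_label)


def _seqnum_of(pos: GenericPosition, nmap: NumberingMap) -> int:
    sn = nmap.residue_at(pos)
    if sn is None:
        raise ValidationError(f"position {pos} not placeable on the synthetic bundle")
    return sn


def _sidechain_in_contact(ra: Residue, rb: Residue, cutoff: float) -> bool:
    for a in ra.sidechain_atoms:
        for b in rb.sidechain_atoms:
            if np.linalg.norm(np.asarray(a.coords) - np.asarray(b.coords)) < cutoff:
                return True
    return False


def toggle_contact(
    s: StructureModel,
    pos_a: GenericPosition,
    pos_b: GenericPosition,
    nmap: NumberingMap,
    g: BundleGeometry | None = None,
    t: ContactThresholds | None = None,
) -> None:
    """Flip the side-chain contact status of one generic pair in place.

    If the pair is currently in contact, both side chains are reset to
    the default outward stub; otherwise they are rebuilt as carbon chains
    reaching toward each other to 0.6 A inside the carbon-carbon vdW-sum
    cutoff.  Applying the toggle twice restores the original coordinates.
    """
    g = g or BundleGeometry()
    t = t or ContactThresholds()
    cc_cutoff = 2 * 1.70 + t.vdw_tolerance
    sa, sb = _seqnum_of(pos_a, nmap), _seqnum_of(pos_b, nmap)
    ra = next(r for r in s.residues if r.seqnum == sa)
    rb = next(r for r in s.residues if r.seqnum == sb)

    def _reset(res: Residue) -> None:
        h = (res.seqnum - 1) // g.residues_per_helix + 1
        i = (res.seqnum - 1) % g.residues_per_helix
        fresh = _make_residue(h, i, res.seqnum, "LEU", g)
        res.name3 = "LEU"
        res.atoms = fresh.atoms

    if _sidechain_in_contact(ra, rb, cc_cutoff):
        _reset(ra)
        _reset(rb)
    else:
        ca_a, ca_b = ra.ca.xyz, rb.ca.xyz
        u = (ca_b - ca_a) / np.linalg.norm(ca_b - ca_a)
        mid = (ca_a + ca_b) / 2.0
        tip_a, tip_b = mid - 1.7 * u, mid + 1.7 * u
        for res, ca, tip, sign in ((ra, ca_a, tip_a, 1.0), (rb, ca_b, tip_b, -1.0)):
            h = (res.seqnum - 1) // g.residues_per_helix + 1
            i = (res.seqnum - 1) % g.residues_per_helix
            cb = ca + 1.53 * sign * u
            cg = (cb + tip) / 2.0
            sc = [("CB", "C", cb), ("CG", "C", cg), ("CD1", "C", tip)]
            fresh = _make_residue(h, i, res.seqnum, "LEU", g, sidechain=sc)
            res.name3 = "LEU"
            res.atoms = fresh.atoms


def gen_state_pair(
    seed: int,
    rewired: list[tuple[GenericPosition, GenericPosition]],
    receptor: str = "synthR",
    geometry: BundleGeometry | None = None,
    thresholds: ContactThresholds | None = None,
):
    """Active/inactive bundle pair differing by the listed rewired contacts.

    The inactive structure is the bare bundle; the active one has each
    listed generic pair's side chains displaced to flip its contact
    status, with a margin of at least 0.5 A beyond the vdW-sum rule.  The
    generated pair is verified by brute force: the active/inactive
    contact-map difference must be exactly the planted pairs.
    """
    from gpcreval.activation import StatePair
    from gpcreval.contacts import build_contact_map, diff_contact_maps

    g = geometry or BundleGeometry()
    t = thresholds or ContactThresholds()
    nmap = synthetic_numbering(g.residues_per_helix)

    involved: list[int] = []
    for pa, pb in rewired:
        for sn in (_seqnum_of(pa, nmap), _seqnum_of(pb, nmap)):
            for prev in involved:
                if sn == prev or abs(sn - prev) < t.min_seq_separation:
                    raise GenerationError(
                        f"rewired residues {sn} and {prev} interfere (same or near in sequence)"
                    )
            involved.append(sn)

    inactive = _bare_bundle(g, f"{receptor}-inactive-{seed}", "inactive")
    active = _bare_bundle(g, f"{receptor}-active-{seed}", "active")
    for pa, pb in rewired:
        toggle_contact(active, pa, pb, nmap, g, t)
    _renumber_serials(active.residues, [])

    cm_a = build_contact_map(active, t=t)
    cm_i = build_contact_map(inactive, t=t)
    gained, lost, _ = diff_contact_maps(cm_a, cm_i, nmap, nmap)
    want = {frozenset((pa, pb)) for pa, pb in rewired}
    if gained | lost != want or (gained & lost):
        raise GenerationError(
            f"planted rewiring not realized: planted {want}, got gained={gained} lost={lost}"
        )
    return StatePair(
        receptor=receptor,
        active=active,
        inactive=inactive,
        numbering_active=nmap,
        numbering_inactive=nmap,
        provenance="synthetic",
    )


def sample_rewirable_pairs(
    seed: int,
    n: int,
    residues_per_helix: int = 24,
) -> list[tuple[GenericPosition, GenericPosition]]:
    """Sample ``n`` mutually non-interfering generic pairs on adjacent helices.

    Adjacent-helix pairs keep the bridging side chains short and away
    from the bundle core, so planted rewirings never create spurious
    contacts elsewhere.
    """
    rng = np.random.default_rng(seed)
    rph = residues_per_helix
    anchor = rph // 2
    g = BundleGeometry(residues_per_helix=rph)
    cc_cutoff = 2 * 1.70 + ContactThresholds().vdw_tolerance

    def _bridge_atoms(h: int, i: int, h2: int, j: int) -> list[np.ndarray] | None:
        ca_a, ca_b = _ca_position(h, i, g), _ca_position(h2, j, g)
        u = ca_b - ca_a
        u = u / np.linalg.norm(u)
        mid = (ca_a + ca_b) / 2.0
        tip_a, tip_b = mid - 1.7 * u, mid + 1.7 * u
        cb_a, cb_b = ca_a + 1.53 * u, ca_b - 1.53 * u
        return [cb_a, (cb_a + tip_a) / 2.0, tip_a, cb_b, (cb_b + tip_b) / 2.0, tip_b]

    def _clear(sides: list[tuple[int, list[np.ndarray]]], others: list[np.ndarray]) -> bool:
        # no bridge atom may come near any third-party stub (or another
        # bridge); residues within the sequence-separation window of a bridge
        # residue are exempt from that residue's own atoms only
        for hh in range(1, 8):
            for ii in range(rph):
                sn = (hh - 1) * rph + ii + 1
                ca = _ca_position(hh, ii, g)
                cb = ca + 1.53 * _radial_out(ca)
                for owner, atoms in sides:
                    if abs(sn - owner) < 4:
                        continue
                    for x in atoms:
                        if np.linalg.norm(x - cb) < cc_cutoff + 0.3:
                            return False
        flat = [x for _, atoms in sides for x in atoms]
        for y in others:
            for x in flat:
                if np.linalg.norm(x - y) < cc_cutoff + 0.3:
                    return False
        return True

    chosen: list[tuple[GenericPosition, GenericPosition]] = []
    used: list[int] = []
    accepted_atoms: list[np.ndarray] = []
    helices = rng.permutation(7) + 1
    for h in helices:
        if len(chosen) >= n:
            break
        h2 = int(h) % 7 + 1
        for _attempt in range(12):
            i = int(rng.integers(3, rph - 3))
            # partner residue at the nearest z level on the adjacent helix, so
            # the bridging side chains stay short and local
            zi = _ca_position(int(h), i, g)[2]
            j0 = min(range(rph), key=lambda j: abs(_ca_position(h2, j, g)[2] - zi))
            j = int(np.clip(j0 + int(rng.integers(-1, 2)), 1, rph - 2))
            sn1 = (int(h) - 1) * rph + i + 1
            sn2 = (h2 - 1) * rph + j + 1
            if any(abs(sn - prev) < 4 for sn in (sn1, sn2) for prev in used):
                continue
            atoms = _bridge_atoms(int(h), i, h2, j)
            if not _clear([(sn1, atoms[:3]), (sn2, atoms[3:])], accepted_atoms):
                continue
            used += [sn1, sn2]
            accepted_atoms += atoms
            chosen.append(
                (GenericPosition(int(h), 50 + i - anchor), GenericPosition(h2, 50 + j - anchor))
            )
            break
    if len(chosen) < n:
        raise GenerationError(f"could only sample {len(chosen)} of {n} rewirable pairs")
    return chosen


__all__ = [
    "BundleGeometry",
    "ComplexTruth",
    "ScenarioTruth",
    "synthetic_template",
    "synthetic_annotation",
    "synthetic_numbering",
    "gen_bundle_complex",
    "gen_mutagenesis_table",
    "gen_family_msa",
    "gen_state_pair",
    "sample_rewirable_pairs",
    "toggle_contact",
    "AA3_TO_1",
    "AA1_TO_3",
]
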