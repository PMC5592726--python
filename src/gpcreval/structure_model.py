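"""Structures, chemistry flags, van der Waals radii, and bundle geometry.

Structures are plain containers parsed from fixed-column PDB text (via
gemmi).  Hydrogens are carried through parsing but ignored by every
distance computation: the models this package evaluates are heavy-atom
homology models, and ligand protonation chemistry enters through the
:class:`LigandDescriptor` flags instead of explicit hydrogens.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

from gpcreval.errors import EmptySelectionError, PdbParseError, ValidationError

log = logging.getLogger(__name__)

#: Atom names that constitute the peptide backbone; everything else is side chain.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: Residue names treated as water and excluded from all contact computations.
WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O", "TIP", "TIP3"})

#: Residue id: (chain, seqnum, insertion code).
ResidueId = tuple[str, int, str]


@dataclass(frozen=True)
class Atom:
    """One atom of a structure.

    ``record_class`` partitions atoms into ``polymer`` (ATOM records),
    ``hetero`` (HETATM, non-water) and ``water``.
    """

    serial: int
    name: str
    element: str
    coords: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""
    record_class: str = "polymer"

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.coords):
            raise ValidationError(f"atom {self.name}: non-finite coordinates {self.coords}")
        if not self.element:
            raise ValidationError(f"atom {self.name}: empty element symbol")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValidationError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")
        if self.record_class not in ("polymer", "hetero", "water"):
            raise ValidationError(f"atom {self.name}: bad record_class {self.record_class!r}")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    """A residue (or hetero group) with its ordered atom list."""

    chain: str
    seqnum: int
    icode: str
    name3: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def rid(self) -> ResidueId:
        return (self.chain, self.seqnum, self.icode)

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    @property
    def backbone_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.name in BACKBONE_ATOMS]

    @property
    def sidechain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.name not in BACKBONE_ATOMS]

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Residue {self.name3} {self.chain}{self.seqnum}{self.icode}>"


@dataclass
class StructureModel:
    """A parsed 3-D structure with the polymer/hetero/water partition applied.

    ``residues`` holds polymer residues in file order; ``ligands`` holds
    non-water hetero groups.  Waters are dropped: every downstream contact
    computation operates on dry models.
    """

    id: str
    residues: list[Residue]
    ligands: list[Residue] = field(default_factory=list)
    state_label: str = "unspecified"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"structure {self.id!r}: no polymer residues")
        if self.state_label not in ("active", "inactive", "unspecified"):
            raise ValidationError(f"structure {self.id!r}: bad state_label {self.state_label!r}")
        seen: set[ResidueId] = set()
        for r in list(self.residues) + list(self.ligands):
            if r.rid in seen:
                raise ValidationError(f"structure {self.id!r}: duplicate residue id {r.rid}")
            seen.add(r.rid)

    def residue(self, rid: ResidueId) -> Residue | None:
        for r in self.residues:
            if r.rid == rid:
                return r
        return None

    @property
    def residue_ids(self) -> list[ResidueId]:
        return [r.rid for r in self.residues]


# ---------------------------------------------------------------------------
# van der Waals radii
# ---------------------------------------------------------------------------

#: Bondi-style radii in Angstrom for the elements that occur in protein/ligand
#: heavy-atom models.
DEFAULT_VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}


@dataclass
class VdwTable:
    """Element -> van der Waals radius (A)."""

    radii: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VDW_RADII))

    def __post_init__(self) -> None:
        self.radii = {k.upper(): float(v) for k, v in self.radii.items()}
        for el in ("C", "N", "O", "S", "P", "H"):
            if el not in self.radii:
                raise ValidationError(f"vdW table missing element {el}")
        for el, r in self.radii.items():
            if r <= 0:
                raise ValidationError(f"vdW radius for {el} must be > 0, got {r}")

    @classmethod
    def from_tsv(cls, source) -> "VdwTable":
        """Read a two-column (element, radius) TSV, header optional."""
        df = pd.read_csv(source, sep="\t", comment="#", header=None, names=["element", "radius"])
        if isinstance(df.iloc[0, 1], str):  # header row present
            df = df.iloc[1:]
        return cls(radii={str(e): float(r) for e, r in zip(df["element"], df["radius"])})

    def radius(self, atom: Atom) -> float:
        el = atom.element.upper()
        if el in self.radii:
            return self.radii[el]
        # Unknown element on a hetero atom: fall back to the first letter of
        # the atom name (e.g. "C7A" -> C) and warn.
        guess = next((c for c in atom.name if c.isalpha()), "").upper()
        if guess in self.radii:
            log.warning("unknown element %r for atom %s: using radius of %s", el, atom.name, guess)
            return self.radii[guess]
        log.warning("unknown element %r for atom %s: using carbon radius", el, atom.name)
        return self.radii["C"]


# ---------------------------------------------------------------------------
# Ligand chemistry descriptor
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LigandAtomChem:
    """Chemistry flags for one ligand atom."""

    formal_charge: int = 0
    ring_id: int | None = None
    hb_donor: bool = False
    hb_acceptor: bool = False
    apolar_carbon: bool = False


@dataclass
class LigandDescriptor:
    """Per-atom ligand chemistry, keyed by atom name.

    Ligand chemistry is always declared, never perceived from geometry;
    this sidesteps bond-perception ambiguity in docked heavy-atom poses.
    """

    atoms: dict[str, LigandAtomChem]

    def __post_init__(self) -> None:
        rings: dict[int, int] = {}
        for info in self.atoms.values():
            if info.ring_id is not None:
                rings[info.ring_id] = rings.get(info.ring_id, 0) + 1
        for rid, n in rings.items():
            if n < 5:
                raise ValidationError(f"ring_id {rid} groups only {n} atoms (need >= 5)")

    def ring_groups(self) -> dict[int, list[str]]:
        groups: dict[int, list[str]] = {}
        for name, info in self.atoms.items():
            if info.ring_id is not None:
                groups.setdefault(info.ring_id, []).append(name)
        return groups

    def validate_against(self, ligand: Residue) -> None:
        """Check that every keyed atom exists in the ligand residue and
        that apolar flags sit on carbons; raise listing the offenders."""
        present = {a.name: a for a in ligand.heavy_atoms}
        missing_in_res = sorted(set(self.atoms) - set(present))
        if missing_in_res:
            raise ValidationError(
                f"descriptor atoms absent from ligand {ligand.name3}: {', '.join(missing_in_res)}"
            )
        uncovered = sorted(set(present) - set(self.atoms))
        if uncovered:
            raise ValidationError(
                f"ligand atoms missing from descriptor: {', '.join(uncovered)}"
            )
        bad = [n for n, i in self.atoms.items() if i.apolar_carbon and present[n].element.upper() != "C"]
        if bad:
            raise ValidationError(f"apolar_carbon flag on non-carbon atoms: {', '.join(sorted(bad))}")

    @classmethod
    def from_tsv(cls, source) -> "LigandDescriptor":
        """Read `atom_name charge ring_id donor acceptor apolar` TSV ('-' = no ring)."""
        df = pd.read_csv(source, sep="\t", dtype=str).fillna("-")
        required = ["atom_name", "charge", "ring_id", "donor", "acceptor", "apolar"]
        if list(df.columns) != required:
            raise ValidationError(f"descriptor columns must be {required}, got {list(df.columns)}")
        atoms = {}
        for _, row in df.iterrows():
            atoms[row["atom_name"]] = LigandAtomChem(
                formal_charge=int(row["charge"]),
                ring_id=None if row["ring_id"] in ("-", "") else int(row["ring_id"]),
                hb_donor=row["donor"] in ("1", "true", "True"),
                hb_acceptor=row["acceptor"] in ("1", "true", "True"),
                apolar_carbon=row["apolar"] in ("1", "true", "True"),
            )
        return cls(atoms=atoms)

    def to_tsv(self) -> str:
        lines = ["atom_name\tcharge\tring_id\tdonor\tacceptor\tapolar"]
        for name in self.atoms:
            i = self.atoms[name]
            ring = "-" if i.ring_id is None else str(i.ring_id)
            lines.append(
                f"{name}\t{i.formal_charge}\t{ring}\t{int(i.hb_donor)}\t{int(i.hb_acceptor)}\t{int(i.apolar_carbon)}"
            )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Contact thresholds
# ---------------------------------------------------------------------------


@dataclass
class ContactThresholds:
    """Distance cutoffs (A) for contact detection and interaction typing.

    ``ligand_contact_cutoff`` is the overall protein-ligand contact rule
    (5.5 A); the per-interaction cutoffs codify the classical chemical
    interaction classes.  ``vdw_tolerance`` softens the van-der-Waals-sum
    residue-residue contact rule; setting it to 0 recovers the strict
    "shorter than the sum of the radii" form.
    """

    ligand_contact_cutoff: float = 5.5
    hbond_max: float = 3.5
    salt_bridge_max: float = 4.0
    ring_centroid_max: float = 5.0
    hydrophobic_max: float = 4.5
    vdw_tolerance: float = 0.6
    min_seq_separation: int = 4

    def __post_init__(self) -> None:
        for name in (
            "ligand_contact_cutoff",
            "hbond_max",
            "salt_bridge_max",
            "ring_centroid_max",
            "hydrophobic_max",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.vdw_tolerance < 0:
            raise ValidationError("vdw_tolerance must be >= 0")
        if self.min_seq_separation < 0:
            raise ValidationError("min_seq_separation must be >= 0")
        for name in ("hbond_max", "salt_bridge_max", "hydrophobic_max", "ring_centroid_max"):
            if getattr(self, name) > self.ligand_contact_cutoff:
                raise ValidationError(
                    f"{name} ({getattr(self, name)}) exceeds ligand_contact_cutoff "
                    f"({self.ligand_contact_cutoff})"
                )


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------


def _validate_pdb_lines(pdb_text: str) -> None:
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line) < 54:
            raise PdbParseError(f"line {lineno}: coordinate record too short")
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                float(line[lo:hi])
            except ValueError:
                raise PdbParseError(
                    f"line {lineno}: malformed {what} coordinate field {line[lo:hi]!r}"
                ) from None


def _select_altloc(atoms: list[gemmi.Atom], policy: str) -> gemmi.Atom:
    if len(atoms) == 1:
        return atoms[0]
    if policy == "first":
        return atoms[0]
    if policy == "highest_occupancy":
        # highest occupancy wins; ties go to the alphabetically first altloc
        return sorted(atoms, key=lambda a: (-a.occ, a.altloc or "~"))[0]
    raise ValidationError(f"unknown altloc policy {policy!r}")


def parse_structure(
    pdb_text: str,
    altloc_policy: str = "highest_occupancy",
    structure_id: str = "model",
    state_label: str = "unspecified",
) -> StructureModel:
    """Parse fixed-column PDB text into a :class:`StructureModel`.

    Atoms are partitioned into polymer/hetero/water by record type and
    residue name; exactly one conformer per atom is retained according to
    ``altloc_policy`` (``highest_occupancy`` or ``first``); waters are
    dropped.
    """
    _validate_pdb_lines(pdb_text)
    st = gemmi.read_pdb_string(pdb_text)
    st.setup_entities()
    residues: list[Residue] = []
    ligands: list[Residue] = []
    n_atoms = 0
    for model in st:
        for chain in model:
            for res in chain:
                is_water = res.name.upper() in WATER_NAMES
                is_het = res.het_flag == "H"
                if is_water:
                    continue
                record_class = "hetero" if is_het else "polymer"
                by_name: dict[str, list[gemmi.Atom]] = {}
                for a in res:
                    by_name.setdefault(a.name, []).append(a)
                atoms = []
                for name, group in by_name.items():
                    a = _select_altloc(group, altloc_policy)
                    el = a.element.name.upper() if a.element and a.element.name != "X" else ""
                    if not el:
                        el = next((c for c in name if c.isalpha()), "C").upper()
                        log.warning("atom %s in %s: element inferred from name -> %s", name, res.name, el)
                    atoms.append(
                        Atom(
                            serial=a.serial,
                            name=name,
                            element=el,
                            coords=(a.pos.x, a.pos.y, a.pos.z),
                            occupancy=min(max(a.occ, 0.0), 1.0),
                            # gemmi encodes "no altloc" as NUL
                            altloc=a.altloc if a.altloc not in ("", "\0") else "",
                            record_class=record_class,
                        )
                    )
                atoms.sort(key=lambda a: a.serial)
                n_atoms += len(atoms)
                icode = res.seqid.icode.strip()
                rr = Residue(chain=chain.name, seqnum=res.seqid.num, icode=icode, name3=res.name, atoms=atoms)
                (ligands if is_het else residues).append(rr)
        break  # first model only
    if n_atoms == 0:
        raise PdbParseError("empty structure: no ATOM/HETATM records")
    if not residues:
        raise PdbParseError("structure contains no polymer residues")
    return StructureModel(id=structure_id, residues=residues, ligands=ligands, state_label=state_label)


def _pdb_atom_name(name: str) -> str:
    # standard alignment: 1-2 letter elements start in column 14
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def write_pdb(s: StructureModel) -> str:
    """Serialize a structure back to fixed-column PDB text (deterministic)."""
    out = io.StringIO()
    serial = 0
    for res in s.residues:
        for a in res.atoms:
            serial += 1
            out.write(
                "ATOM  %5d %s%1s%3s %1s%4d%1s   %8.3f%8.3f%8.3f%6.2f%6.2f          %2s\n"
                % (
                    serial,
                    _pdb_atom_name(a.name),
                    a.altloc or " ",
                    res.name3[:3],
                    res.chain[:1],
                    res.seqnum,
                    res.icode or " ",
                    a.coords[0],
                    a.coords[1],
                    a.coords[2],
                    a.occupancy,
                    0.0,
                    a.element[:2].rjust(2),
                )
            )
    out.write("TER\n")
    for res in s.ligands:
        for a in res.atoms:
            serial += 1
            out.write(
                "HETATM%5d %s%1s%3s %1s%4d%1s   %8.3f%8.3f%8.3f%6.2f%6.2f          %2s\n"
                % (
                    serial,
                    _pdb_atom_name(a.name),
                    a.altloc or " ",
                    res.name3[:3],
                    res.chain[:1],
                    res.seqnum,
                    res.icode or " ",
                    a.coords[0],
                    a.coords[1],
                    a.coords[2],
                    a.occupancy,
                    0.0,
                    a.element[:2].rjust(2),
                )
            )
    out.write("END\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def _filtered_heavy(res: Residue, atom_filter: str) -> list[Atom]:
    if atom_filter == "all":
        return res.heavy_atoms
    if atom_filter == "sidechain_only":
        return [a for a in res.heavy_atoms if a.name not in BACKBONE_ATOMS]
    raise ValidationError(f"unknown atom filter {atom_filter!r}")


def min_heavy_atom_distance(a: Residue, b: Residue, atom_filter: str = "all") -> float:
    """Minimum pairwise Euclidean distance (A) over non-hydrogen atoms.

    Raises :class:`EmptySelectionError` when either residue has no atom
    surviving the filter (e.g. Gly under ``sidechain_only``) so that an
    empty selection is never confused with a large distance.
    """
    atoms_a = _filtered_heavy(a, atom_filter)
    atoms_b = _filtered_heavy(b, atom_filter)
    if not atoms_a or not atoms_b:
        raise EmptySelectionError(
            f"no atoms survive filter {atom_filter!r} for pair "
            f"({a.name3} {a.chain}{a.seqnum}, {b.name3} {b.chain}{b.seqnum})"
        )
    xa = np.array([at.coords for at in atoms_a], dtype=float)
    xb = np.array([at.coords for at in atoms_b], dtype=float)
    d2 = ((xa[:, None, :] - xb[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min()))


def bundle_axis(structure: StructureModel, tm_residues) -> tuple[np.ndarray, np.ndarray]:
    """Principal axis and centroid of the Calpha cloud of ``tm_residues``.

    The axis is the first principal direction, with its sign chosen so
    that the most N-terminal residue of the set projects positively
    (class A topology: the N-terminus is extracellular, so positive
    projections are the extracellular / "top" half).
    """
    wanted: list[Residue] = []
    tm = set(tm_residues)
    for r in structure.residues:
        if r.rid in tm or r.seqnum in tm:
            wanted.append(r)
    cas = [(r, r.ca) for r in wanted if r.ca is not None]
    if len(cas) < 3:
        raise ValidationError(f"bundle_axis needs >= 3 Calpha atoms, got {len(cas)}")
    coords = np.array([a.xyz for _, a in cas])
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, sing, vt = np.linalg.svd(centered, full_matrices=False)
    if sing[0] < 1e-8:
        raise ValidationError("degenerate Calpha coordinates: all points coincide")
    axis = vt[0]
    first = min(cas, key=lambda rc: (rc[0].chain, rc[0].seqnum, rc[0].icode))
    proj = float((first[1].xyz - centroid) @ axis)
    if proj < 0:
        axis = -axis
    return axis, centroid


__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "VdwTable",
    "LigandAtomChem",
    "LigandDescriptor",
    "ContactThresholds",
    "ResidueId",
    "BACKBONE_ATOMS",
    "DEFAULT_VDW_RADII",
    "parse_structure",
    "write_pdb",
    "min_heavy_atom_distance",
    "bundle_axis",
]
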