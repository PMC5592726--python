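"""Family-alignment conservation, conserved-motif scanning, and curation.

An :class:`AlignedFamily` is a fixed multiple sequence alignment whose
columns are mapped to generic positions through the reference row, so
that "what fraction of the family carries Asn at 1.50" is a single
column query.  Motifs are small sets of (position, allowed residues)
constraints, e.g. the TM3 D[E]R Y triad of class A receptors; they drive
both conservation reporting and the curation filter that discards
probable pseudogene / misannotated rows (large gaps or missing conserved
features).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import yaml
from Bio import SeqIO

from gpcreval.errors import ValidationError
from gpcreval.numbering import (
    GenericPosition,
    NumberingMap,
    ReferenceAnnotation,
    assign_generic_numbers,
)

GAP = "-"


@dataclass
class AlignedFamily:
    """An MSA with a column -> generic-position map via the reference row."""

    rows: list[tuple[str, str]]
    reference_id: str
    column_positions: dict[int, GenericPosition] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValidationError("alignment has no rows")
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) != 1:
            raise ValidationError(f"alignment rows differ in length: {sorted(lengths)}")
        if self.reference_id not in {rid for rid, _ in self.rows}:
            raise ValidationError(f"reference row {self.reference_id!r} not in alignment")
        if len(set(self.column_positions.values())) != len(self.column_positions):
            raise ValidationError("column -> position map is not injective")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    def column_of(self, pos: GenericPosition) -> int:
        for col, gp in self.column_positions.items():
            if gp == pos:
                return col
        raise ValidationError(f"position {pos} is not mapped to any alignment column")

    @property
    def tm_columns(self) -> list[int]:
        return sorted(self.column_positions)

    @classmethod
    def from_alignment(
        cls,
        rows: list[tuple[str, str]],
        reference_id: str,
        ann: ReferenceAnnotation,
    ) -> "AlignedFamily":
        """Build the column map by numbering the reference row against itself."""
        ref_row = dict(rows).get(reference_id)
        if ref_row is None:
            raise ValidationError(f"reference row {reference_id!r} not in alignment")
        nmap: NumberingMap = assign_generic_numbers(ref_row, ref_row, ann)
        # reference residue i (1-based) sits at the i-th non-gap column
        col_positions: dict[int, GenericPosition] = {}
        ref_idx = 0
        for col, ch in enumerate(ref_row):
            if ch == GAP:
                continue
            ref_idx += 1
            gp = nmap.position_of(ref_idx)
            if gp is not None:
                col_positions[col] = gp
        return cls(rows=rows, reference_id=reference_id, column_positions=col_positions)

    @classmethod
    def from_fasta(cls, source, reference_id: str, ann: ReferenceAnnotation) -> "AlignedFamily":
        rows = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(source, "fasta")]
        return cls.from_alignment(rows, reference_id, ann)

    def to_fasta(self) -> str:
        return "".join(f">{rid}\n{seq}\n" for rid, seq in self.rows)


@dataclass
class MotifSpec:
    """A named set of (generic position, allowed residues) constraints."""

    name: str
    constraints: list[tuple[GenericPosition, frozenset[str]]]
    family: str = ""

    def __post_init__(self) -> None:
        positions = [p for p, _ in self.constraints]
        if len(set(positions)) != len(positions):
            raise ValidationError(f"motif {self.name!r}: duplicate positions")
        for p, allowed in self.constraints:
            if not allowed:
                raise ValidationError(f"motif {self.name!r}: empty allowed set at {p}")


@dataclass
class ConservationResult:
    position: GenericPosition
    residues: frozenset[str]
    count: int
    total: int

    def __post_init__(self) -> None:
        if not 0 <= self.count <= self.total:
            raise ValidationError(f"count {self.count} outside [0, {self.total}]")

    @property
    def fraction(self) -> Fraction:
        return Fraction(self.count, self.total) if self.total else Fraction(0)

    @property
    def percentage(self) -> float:
        return 100.0 * self.count / self.total if self.total else 0.0

    @property
    def percentage_1dp(self) -> float:
        return round(self.percentage, 1)


def conservation_at(
    f: AlignedFamily,
    pos: GenericPosition,
    residues,
) -> ConservationResult:
    """Fraction of the family carrying one of ``residues`` at ``pos``.

    The denominator counts rows without a gap at the column: conservation
    is measured among sequences that possess the position.
    """
    col = f.column_of(pos)
    wanted = frozenset(r.upper() for r in residues)
    count = 0
    total = 0
    for _, seq in f.rows:
        ch = seq[col].upper()
        if ch == GAP:
            continue
        total += 1
        if ch in wanted:
            count += 1
    return ConservationResult(position=pos, residues=wanted, count=count, total=total)


def scan_motif(f: AlignedFamily, m: MotifSpec) -> tuple[dict[str, bool], float]:
    """Per-row pass flags plus the family pass fraction.

    A row passes iff every constraint is satisfied; a gap at any
    constrained column fails the row.
    """
    cols = []
    for pos, allowed in m.constraints:
        try:
            cols.append((f.column_of(pos), allowed))
        except ValidationError:
            raise ValidationError(f"motif {m.name!r}: position {pos} is unmapped") from None
    flags: dict[str, bool] = {}
    for rid, seq in f.rows:
        flags[rid] = all(seq[col].upper() in allowed for col, allowed in cols)
    frac = sum(flags.values()) / len(flags) if flags else 0.0
    return flags, frac


@dataclass
class CurationResult:
    retained: list[str]
    rejections: dict[str, str]


def curate_family(
    f: AlignedFamily,
    gap_frac_max: float = 0.2,
    required: list[MotifSpec] | None = None,
    min_motifs: int | None = None,
) -> CurationResult:
    """Discard rows with large TM gaps or missing conserved features.

    A row is discarded iff its gap fraction over mapped TM columns
    exceeds ``gap_frac_max``, or it passes fewer than ``min_motifs`` of
    the ``required`` motifs (default: all of them).  The reference row is
    subject to the same rules.
    """
    if not 0 < gap_frac_max <= 1:
        raise ValidationError("gap_frac_max must be in (0, 1]")
    required = required or []
    if min_motifs is None:
        min_motifs = len(required)
    tm_cols = f.tm_columns
    motif_flags = [scan_motif(f, m)[0] for m in required]

    retained: list[str] = []
    rejections: dict[str, str] = {}
    for rid, seq in f.rows:
        if tm_cols:
            gap_frac = sum(1 for c in tm_cols if seq[c] == GAP) / len(tm_cols)
        else:
            gap_frac = 0.0
        if gap_frac > gap_frac_max:
            rejections[rid] = "gap fraction"
            continue
        n_pass = sum(flags[rid] for flags in motif_flags)
        if n_pass < min_motifs:
            rejections[rid] = "missing conserved features"
            continue
        retained.append(rid)
    return CurationResult(retained=retained, rejections=rejections)


# ---------------------------------------------------------------------------
# Shipped motif definitions and residue classes
# ---------------------------------------------------------------------------


def _mk(name: str, family: str, *constraints: tuple[str, str]) -> MotifSpec:
    return MotifSpec(
        name=name,
        family=family,
        constraints=[(GenericPosition.parse(p), frozenset(a)) for p, a in constraints],
    )


#: Conserved TM motifs of class A GPCRs (N1.50, the D[E]RY triad, W4.50,
#: P5.50, the CWxP region, and the NPxxY motif).
CLASS_A_MOTIFS: list[MotifSpec] = [
    _mk("TM1_N1.50", "classA", ("1.50", "N"), ("1.53", "V")),
    _mk("TM2_LxxxD", "classA", ("2.46", "L"), ("2.50", "D")),
    _mk("TM3_DRY", "classA", ("3.49", "DE"), ("3.50", "R"), ("3.51", "Y")),
    _mk("TM4_W4.50", "classA", ("4.50", "W")),
    _mk("TM5_P5.50", "classA", ("5.50", "P")),
    _mk("TM6_FxxxW", "classA", ("6.44", "F"), ("6.48", "W"), ("6.50", "P")),
    _mk("TM7_NPxxY", "classA", ("7.49", "N"), ("7.50", "P"), ("7.53", "Y")),
]

#: Conserved TM motifs of the bitter taste receptor family.
TAS2R_MOTIFS: list[MotifSpec] = [
    _mk("TM1_NxxI", "hTAS2R", ("1.50", "N"), ("1.53", "I")),
    _mk("TM2_LxxxR", "hTAS2R", ("2.46", "L"), ("2.50", "R")),
    _mk("TM3_LxxFYxxK", "hTAS2R", ("3.46", "L"), ("3.49", "F"), ("3.50", "Y"), ("3.53", "K")),
    _mk("TM5_LxxSL_P", "hTAS2R", ("5.39", "L"), ("5.42", "S"), ("5.43", "L"), ("5.50", "P")),
    _mk("TM6_FxxxY", "hTAS2R", ("6.44", "F"), ("6.48", "Y")),
    _mk("TM7_HSxIVL", "hTAS2R", ("7.49", "H"), ("7.50", "S"), ("7.52", "IV"), ("7.53", "L")),
]

#: Conserved TM motifs of the odorant receptor family.
OR_MOTIFS: list[MotifSpec] = [
    _mk("TM1_GNxxI", "hOR", ("1.49", "G"), ("1.50", "N"), ("1.53", "I")),
    _mk("TM2_LSxxD", "hOR", ("2.46", "L"), ("2.47", "S"), ("2.50", "D")),
    _mk("TM3_DRY", "hOR", ("3.49", "DE"), ("3.50", "R"), ("3.51", "Y")),
    _mk("TM4_W4.50", "hOR", ("4.50", "W")),
    _mk("TM7_NPxILY", "hOR", ("7.49", "N"), ("7.50", "P"), ("7.52", "IL"), ("7.53", "Y")),
]

#: Residue classes for class-level conservation queries (e.g. branched
#: aliphatic conservation at 7.52).
RESIDUE_CLASSES: dict[str, frozenset[str]] = {
    "branched_aliphatic": frozenset("VLI"),
    "hydrophobic": frozenset("AVLIMFWC"),
    "aromatic": frozenset("FYWH"),
    "positive": frozenset("KRH"),
    "negative": frozenset("DE"),
    "polar": frozenset("STNQYC"),
    "small": frozenset("AGS"),
}


def motifs_from_yaml(source) -> list[MotifSpec]:
    """Read motif specs from YAML: a list of {name, family, constraints:
    [{position, allowed}]} entries."""
    data = yaml.safe_load(source.read() if hasattr(source, "read") else open(source).read())
    motifs = []
    for entry in data:
        motifs.append(
            MotifSpec(
                name=entry["name"],
                family=entry.get("family", ""),
                constraints=[
                    (GenericPosition.parse(c["position"]), frozenset(str(c["allowed"]).upper()))
                    for c in entry["constraints"]
                ],
            )
        )
    return motifs


__all__ = [
    "AlignedFamily",
    "MotifSpec",
    "ConservationResult",
    "CurationResult",
    "conservation_at",
    "scan_motif",
    "curate_family",
    "CLASS_A_MOTIFS",
    "TAS2R_MOTIFS",
    "OR_MOTIFS",
    "RESIDUE_CLASSES",
    "motifs_from_yaml",
]
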