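"""Generic (Ballesteros-Weinstein / GPCRdb-style) residue numbering.

Each transmembrane helix carries a most-conserved anchor residue labelled
X.50; every other helix residue is numbered by its signed sequence
distance from that anchor (1.53 is three residues C-terminal of the TM1
anchor).  Numbers are projected from a reference template through a
user-supplied alignment, which makes residues comparable across
receptors and to mutagenesis records.  Bulge/constriction adjustments of
the full GPCRdb scheme are deliberately not applied: numbers are plain
offsets from the template anchors.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import yaml

from gpcreval.errors import ValidationError

_POS_RE = re.compile(r"^([1-7])\.(\d{1,2})$")


@dataclass(frozen=True, order=True)
class GenericPosition:
    """A helix.offset label such as 7.52 (anchor offset = 50)."""

    helix: int
    offset: int

    def __post_init__(self) -> None:
        if not 1 <= self.helix <= 7:
            raise ValidationError(f"helix must be 1..7, got {self.helix}")
        if not 1 <= self.offset <= 99:
            raise ValidationError(f"offset must be 1..99, got {self.offset}")

    def __str__(self) -> str:
        return f"{self.helix}.{self.offset:02d}"

    @classmethod
    def parse(cls, text: str) -> "GenericPosition":
        m = _POS_RE.match(text.strip())
        if not m:
            raise ValidationError(f"cannot parse generic position {text!r}")
        return cls(helix=int(m.group(1)), offset=int(m.group(2)))


@dataclass
class ReferenceAnnotation:
    """Template sequence with per-helix TM spans and X.50 anchor indices.

    Spans and anchors are 0-based indices into ``template_seq``; spans are
    half-open ``(start, end)``.
    """

    template_id: str
    template_seq: str
    tm_spans: dict[int, tuple[int, int]]
    anchors: dict[int, int]

    def __post_init__(self) -> None:
        self.tm_spans = {int(h): (int(s), int(e)) for h, (s, e) in self.tm_spans.items()}
        self.anchors = {int(h): int(i) for h, i in self.anchors.items()}
        prev_end = -1
        for h in sorted(self.tm_spans):
            s, e = self.tm_spans[h]
            if not (0 <= s < e <= len(self.template_seq)):
                raise ValidationError(f"TM{h} span ({s},{e}) outside template sequence")
            if s < prev_end:
                raise ValidationError(f"TM{h} span overlaps or precedes the previous span")
            prev_end = e
            if h not in self.anchors:
                raise ValidationError(f"TM{h} has no anchor")
            if not s <= self.anchors[h] < e:
                raise ValidationError(f"TM{h} anchor {self.anchors[h]} outside span ({s},{e})")

    def helix_of_index(self, idx: int) -> int | None:
        for h, (s, e) in self.tm_spans.items():
            if s <= idx < e:
                return h
        return None

    @classmethod
    def from_yaml(cls, source) -> "ReferenceAnnotation":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        return cls(
            template_id=data["template_id"],
            template_seq=data["template_seq"],
            tm_spans={int(h): tuple(v) for h, v in data["tm_spans"].items()},
            anchors={int(h): int(v) for h, v in data["anchors"].items()},
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "template_id": self.template_id,
                "template_seq": self.template_seq,
                "tm_spans": {h: list(v) for h, v in self.tm_spans.items()},
                "anchors": dict(self.anchors),
            },
            sort_keys=True,
        )


@dataclass
class NumberingMap:
    """Bidirectional residue seqnum <-> :class:`GenericPosition` map."""

    pos_by_seqnum: dict[int, GenericPosition] = field(default_factory=dict)
    unmapped: list[int] = field(default_factory=list)
    unmapped_helices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[GenericPosition, int] = {}
        for sn, gp in self.pos_by_seqnum.items():
            if gp in seen:
                raise ValidationError(f"position {gp} assigned to both {seen[gp]} and {sn}")
            seen[gp] = sn
        # offsets must increase with sequence number within each helix
        by_helix: dict[int, list[tuple[int, int]]] = {}
        for sn, gp in self.pos_by_seqnum.items():
            by_helix.setdefault(gp.helix, []).append((sn, gp.offset))
        for h, pairs in by_helix.items():
            pairs.sort()
            offsets = [o for _, o in pairs]
            if offsets != sorted(offsets) or len(set(offsets)) != len(offsets):
                raise ValidationError(f"offsets not strictly increasing with seqnum in TM{h}")
        self._seqnum_by_pos = seen

    def position_of(self, seqnum: int) -> GenericPosition | None:
        return self.pos_by_seqnum.get(seqnum)

    def residue_at(self, pos: GenericPosition) -> int | None:
        """Inverse lookup; ``None`` for unmapped positions."""
        return self._seqnum_by_pos.get(pos)

    def __len__(self) -> int:
        return len(self.pos_by_seqnum)


def residue_at(nmap: NumberingMap, pos: GenericPosition) -> int | None:
    """Functional alias for :meth:`NumberingMap.residue_at`."""
    return nmap.residue_at(pos)


def assign_generic_numbers(
    target_row: str,
    reference_row: str,
    ann: ReferenceAnnotation,
    seq_start: int = 1,
) -> NumberingMap:
    """Project template generic numbers onto a target through an alignment.

    Both rows must come from the same alignment (equal length, ``-`` gaps)
    and the reference row must equal the annotation's template sequence
    once degapped.  A target residue aligned within a TM span receives
    ``offset = 50 + (reference-position distance from the helix anchor)``.
    If the target is gapped at a helix's anchor column, that whole helix
    is left unmapped and reported in ``unmapped_helices``.  Offsets
    falling outside 1..99 leave the residue unmapped rather than clamped.

    ``seq_start`` is the sequence number of the first target residue, so
    map keys line up with structure seqnums.
    """
    if len(target_row) != len(reference_row):
        raise ValidationError(
            f"alignment rows differ in length ({len(target_row)} vs {len(reference_row)})"
        )
    ref_degapped = reference_row.replace("-", "")
    if ref_degapped != ann.template_seq:
        raise ValidationError("reference row does not match the annotation's template sequence")

    # locate each anchor's alignment column and check the target there
    anchor_cols: dict[int, int] = {}
    ref_idx = -1
    for col, ch in enumerate(reference_row):
        if ch == "-":
            continue
        ref_idx += 1
        for h, a in ann.anchors.items():
            if ref_idx == a:
                anchor_cols[h] = col
    for h in ann.anchors:
        if h not in anchor_cols:
            raise ValidationError(f"TM{h} anchor column gapped or absent in reference row")
    dead_helices = sorted(h for h, col in anchor_cols.items() if target_row[col] == "-")

    pos_by_seqnum: dict[int, GenericPosition] = {}
    unmapped: list[int] = []
    ref_idx = -1
    tgt_idx = -1
    for col in range(len(reference_row)):
        rch, tch = reference_row[col], target_row[col]
        if rch != "-":
            ref_idx += 1
        if tch == "-":
            continue
        tgt_idx += 1
        seqnum = seq_start + tgt_idx
        if rch == "-":
            unmapped.append(seqnum)
            continue
        helix = ann.helix_of_index(ref_idx)
        if helix is None or helix in dead_helices:
            unmapped.append(seqnum)
            continue
        offset = 50 + (ref_idx - ann.anchors[helix])
        if not 1 <= offset <= 99:
            unmapped.append(seqnum)
            continue
        pos_by_seqnum[seqnum] = GenericPosition(helix=helix, offset=offset)
    return NumberingMap(
        pos_by_seqnum=pos_by_seqnum, unmapped=unmapped, unmapped_helices=dead_helices
    )


__all__ = [
    "GenericPosition",
    "ReferenceAnnotation",
    "NumberingMap",
    "assign_generic_numbers",
    "residue_at",
]
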