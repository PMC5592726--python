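"""Contact rewiring between active and inactive receptor states.

For each receptor with both an active and an inactive structure, the
side-chain contact maps are built under the vdW-sum rule and diffed in
generic-position space, so that the same interaction change (say,
7.52-1.53 gained upon activation) can be recognized across receptors.
Generic pairs changing in enough receptor pairs are reported with their
gained/lost breakdown; positions are then ranked by how many rewired
pairs involve them, restricted to positions conserved across the family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from gpcreval.contacts import ContactMap, build_contact_map, diff_contact_maps
from gpcreval.conservation import ConservationResult
from gpcreval.errors import ValidationError
from gpcreval.numbering import GenericPosition, NumberingMap
from gpcreval.structure_model import ContactThresholds, StructureModel, VdwTable


@dataclass
class StatePair:
    """Active/inactive structure pair of one receptor, both numbered."""

    receptor: str
    active: StructureModel
    inactive: StructureModel
    numbering_active: NumberingMap
    numbering_inactive: NumberingMap
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.numbering_active) == 0 or len(self.numbering_inactive) == 0:
            raise ValidationError(f"state pair {self.receptor!r}: structures are not numbered")


@dataclass
class RewiredPair:
    """One generic-position pair whose contact status changes on activation."""

    positions: frozenset
    support: int
    gained_in: list[str] = field(default_factory=list)
    lost_in: list[str] = field(default_factory=list)


@dataclass
class RewiringReport:
    pairs: dict[frozenset, RewiredPair]
    n_state_pairs: int
    n_dropped_unmapped: int = 0

    def __post_init__(self) -> None:
        for rp in self.pairs.values():
            if rp.support > self.n_state_pairs:
                raise ValidationError("support exceeds the number of state pairs")

    @property
    def involvement(self) -> dict[GenericPosition, int]:
        """Number of reported pairs each position participates in."""
        counts: dict[GenericPosition, int] = {}
        for key in self.pairs:
            for pos in key:
                counts[pos] = counts.get(pos, 0) + 1
        return counts

    def to_tsv(self) -> str:
        lines = ["position_a\tposition_b\tsupport\tgained_in\tlost_in"]
        for key in sorted(self.pairs, key=lambda k: sorted(k)):
            rp = self.pairs[key]
            a, b = sorted(key)
            gained = ",".join(rp.gained_in) or "-"
            lost = ",".join(rp.lost_in) or "-"
            lines.append(f"{a}\t{b}\t{rp.support}\t{gained}\t{lost}")
        return "\n".join(lines) + "\n"


def aggregate_rewiring(
    pairs: list[StatePair],
    vdw: VdwTable | None = None,
    t: ContactThresholds | None = None,
    min_support: int = 3,
) -> RewiringReport:
    """Aggregate contact-map differences across receptor state pairs.

    A generic pair enters the report iff it changes (gained or lost) in
    at least ``min_support`` receptor pairs.  The default of 3 asks for a
    majority among a typical panel of five receptor pairs.
    """
    if not pairs:
        raise ValidationError("need at least one state pair")
    if min_support < 1:
        raise ValidationError("min_support must be >= 1")
    vdw = vdw or VdwTable()
    t = t or ContactThresholds()

    collected: dict[frozenset, RewiredPair] = {}
    total_dropped = 0
    for sp in pairs:
        cm_active: ContactMap = build_contact_map(sp.active, vdw, t)
        cm_inactive: ContactMap = build_contact_map(sp.inactive, vdw, t)
        gained, lost, dropped = diff_contact_maps(
            cm_active, cm_inactive, sp.numbering_active, sp.numbering_inactive
        )
        total_dropped += dropped
        for key in gained:
            rp = collected.setdefault(key, RewiredPair(positions=key, support=0))
            rp.support += 1
            rp.gained_in.append(sp.receptor)
        for key in lost:
            rp = collected.setdefault(key, RewiredPair(positions=key, support=0))
            rp.support += 1
            rp.lost_in.append(sp.receptor)

    reported = {k: v for k, v in collected.items() if v.support >= min_support}
    return RewiringReport(
        pairs=reported, n_state_pairs=len(pairs), n_dropped_unmapped=total_dropped
    )


def rank_activation_positions(
    report: RewiringReport,
    cons: list[ConservationResult],
    min_conservation: float = 70.0,
) -> tuple[list[GenericPosition], list[GenericPosition]]:
    """Rank reported positions by rewiring involvement among conserved ones.

    Positions at or above ``min_conservation`` percent are ordered by
    involvement count (descending), ties broken by helix then offset;
    positions below the threshold are returned separately.  Conservation
    must be supplied for every reported position.
    """
    by_pos = {c.position: c for c in cons}
    involvement = report.involvement
    missing = sorted(p for p in involvement if p not in by_pos)
    if missing:
        raise ValidationError(
            f"no conservation entry for positions: {', '.join(str(p) for p in missing)}"
        )
    conserved = [p for p in involvement if by_pos[p].percentage >= min_conservation]
    below = sorted(p for p in involvement if by_pos[p].percentage < min_conservation)
    ranked = sorted(conserved, key=lambda p: (-involvement[p], p.helix, p.offset))
    return ranked, below


__all__ = [
    "StatePair",
    "RewiredPair",
    "RewiringReport",
    "aggregate_rewiring",
    "rank_activation_positions",
]
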