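"""Precision/recall evaluation of predicted contacts against mutagenesis data.

Experimentally tested residues in the extracellular ("top") half of the
bundle are classified as TP/FP/TN/FN by agreement between the predicted
ligand contact and the measured EC50 effect:

* TP - mutation affects the response and the residue is a predicted contact;
* FN - mutation affects the response but the residue is not predicted;
* FP - mutation has no effect yet the residue is a predicted contact;
* TN - mutation has no effect and the residue is not predicted.

From these, precision = TP/(TP+FP), recall = TP/(TP+FN), and the
predictive power = (TP+TN)*100 / (number of tested residues in the top
half).  Contacted residues that were never tested are reported
separately and never enter the counts: the denominators are defined by
the experimental data, not by the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from gpcreval.errors import ValidationError
from gpcreval.numbering import GenericPosition
from gpcreval.structure_model import ResidueId, StructureModel

#: EC50 fold-change at or above which a mutation counts as affecting the
#: response when only a fold-change (and no explicit class) is given.
DEFAULT_FOLD_CHANGE_THRESHOLD = 2.0


@dataclass
class MutagenesisRecord:
    """One site-directed mutagenesis measurement."""

    receptor: str
    seqnum: int
    mutation: str
    effect_class: str  # affects_response | no_effect
    generic_position: GenericPosition | None = None
    ec50_fold_change: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.effect_class not in ("affects_response", "no_effect"):
            raise ValidationError(f"bad effect_class {self.effect_class!r}")
        if self.ec50_fold_change is not None and self.ec50_fold_change <= 0:
            raise ValidationError("ec50_fold_change must be positive")


@dataclass
class EvaluationCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.TP, self.FP, self.TN, self.FN)


@dataclass
class EvaluationResult:
    counts: EvaluationCounts
    precision: float
    recall: float
    predictive_power: float
    ledger: list[dict] = field(default_factory=list)
    untested_contacts: list[int] = field(default_factory=list)


def precision(c: EvaluationCounts) -> float:
    """TP/(TP+FP); 0 by convention when nothing was predicted."""
    denom = c.TP + c.FP
    return c.TP / denom if denom else 0.0


def recall(c: EvaluationCounts) -> float:
    """TP/(TP+FN); 0 by convention when nothing was affected."""
    denom = c.TP + c.FN
    return c.TP / denom if denom else 0.0


def predictive_power(c: EvaluationCounts) -> float:
    """(TP+TN)*100 / total tested residues, as a percentage."""
    if c.total == 0:
        raise ValidationError("predictive power undefined: no tested residues")
    return (c.TP + c.TN) * 100.0 / c.total


def round2(x: float) -> float:
    """Round half away from zero to two decimals (report display only)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def top_half_residues(
    s: StructureModel,
    axis: np.ndarray,
    centroid: np.ndarray,
) -> set[ResidueId]:
    """Residues whose Calpha projects on/above the centroid along the axis.

    The axis orientation (from :func:`~gpcreval.structure_model.bundle_axis`)
    points extracellular, so the returned set is the top half of the
    receptor, where the canonical orthosteric site sits.  Residues
    exactly at the midpoint are included; residues without a Calpha are
    excluded with a warning.
    """
    import logging

    log = logging.getLogger(__name__)
    axis = np.asarray(axis, dtype=float)
    centroid = np.asarray(centroid, dtype=float)
    out: set[ResidueId] = set()
    for res in s.residues:
        ca = res.ca
        if ca is None:
            log.warning("residue %s %s%d has no Calpha; excluded from top-half set",
                        res.name3, res.chain, res.seqnum)
            continue
        if float((ca.xyz - centroid) @ axis) >= 0.0:
            out.add(res.rid)
    return out


def _dedupe_records(records: list[MutagenesisRecord]) -> dict[int, str]:
    """Collapse records to one effect class per residue.

    Any affecting mutation makes the residue ``affects_response``
    (worst-case collapse); records with only a fold change are classed by
    the configured threshold upstream, so here effect_class is taken as
    given.
    """
    effect: dict[int, str] = {}
    for rec in records:
        prev = effect.get(rec.seqnum)
        if prev == "affects_response":
            continue
        if rec.effect_class == "affects_response" or prev is None:
            effect[rec.seqnum] = rec.effect_class
    return effect


def evaluate_complex(
    contacts,
    records: list[MutagenesisRecord],
    top_half: set[ResidueId],
    require_chemical: bool = True,
    known_residues: set[int] | None = None,
) -> EvaluationResult:
    """Score predicted contacts against the mutagenesis table.

    ``contacts`` is the output of
    :func:`~gpcreval.contacts.detect_ligand_contacts`; with
    ``require_chemical`` a residue counts as predicted only when its
    contact passes the chemical filter.  Only tested residues whose
    Calpha lies in ``top_half`` enter the confusion matrix.  When
    ``known_residues`` is given, a record referencing a residue outside
    it raises an error listing the offenders.
    """
    if known_residues is not None:
        missing = sorted({r.seqnum for r in records} - set(known_residues))
        if missing:
            raise ValidationError(
                f"mutagenesis records reference residues absent from the structure: {missing}"
            )
    predicted: set[int] = set()
    for c in contacts:
        if not require_chemical or c.passes_chemical_filter:
            predicted.add(c.rid[1])
    top_half_seqnums = {rid[1] for rid in top_half}

    effect = _dedupe_records(records)
    tested = {sn for sn in effect if sn in top_half_seqnums}

    counts = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    ledger = []
    for sn in sorted(tested):
        affected = effect[sn] == "affects_response"
        pred = sn in predicted
        outcome = {
            (True, True): "TP",
            (True, False): "FN",
            (False, True): "FP",
            (False, False): "TN",
        }[(affected, pred)]
        counts[outcome] += 1
        ledger.append(
            {"seqnum": sn, "effect": effect[sn], "predicted": pred, "outcome": outcome}
        )
    ec = EvaluationCounts(**counts)
    untested = sorted(sn for sn in predicted if sn not in effect)
    return EvaluationResult(
        counts=ec,
        precision=precision(ec),
        recall=recall(ec),
        predictive_power=predictive_power(ec) if ec.total else 0.0,
        ledger=ledger,
        untested_contacts=untested,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_mutagenesis_tsv(
    source,
    fold_change_threshold: float = DEFAULT_FOLD_CHANGE_THRESHOLD,
) -> list[MutagenesisRecord]:
    """Read `receptor residue_seqnum generic_position mutation effect ec50_fold source`.

    ``effect`` may be ``affects_response``/``no_effect``, or ``-`` to
    derive the class from the fold change (``abolished`` or a fold change
    at/above the threshold means affects_response).
    """
    df = pd.read_csv(source, sep="\t", dtype=str).fillna("-")
    required = ["receptor", "residue_seqnum", "generic_position", "mutation", "effect", "ec50_fold", "source"]
    if list(df.columns) != required:
        raise ValidationError(f"mutagenesis columns must be {required}, got {list(df.columns)}")
    records = []
    for _, row in df.iterrows():
        fold_raw = row["ec50_fold"]
        abolished = fold_raw.lower() == "abolished"
        fold = None if fold_raw in ("-", "") or abolished else float(fold_raw)
        effect = row["effect"]
        if effect in ("-", ""):
            if abolished:
                effect = "affects_response"
            elif fold is None:
                raise ValidationError(
                    f"record {row['mutation']}: neither effect class nor fold change given"
                )
            else:
                effect = "affects_response" if fold >= fold_change_threshold else "no_effect"
        gp = None if row["generic_position"] in ("-", "") else GenericPosition.parse(row["generic_position"])
        records.append(
            MutagenesisRecord(
                receptor=row["receptor"],
                seqnum=int(row["residue_seqnum"]),
                generic_position=gp,
                mutation=row["mutation"],
                effect_class=effect,
                ec50_fold_change=fold,
                source=row["source"],
            )
        )
    seen = set()
    for rec in records:
        key = (rec.seqnum, rec.mutation)
        if key in seen:
            raise ValidationError(f"duplicate record for residue {rec.seqnum} mutation {rec.mutation}")
        seen.add(key)
    return records


def records_to_tsv(records: list[MutagenesisRecord]) -> str:
    lines = ["receptor\tresidue_seqnum\tgeneric_position\tmutation\teffect\tec50_fold\tsource"]
    for r in records:
        gp = str(r.generic_position) if r.generic_position else "-"
        fold = f"{r.ec50_fold_change:g}" if r.ec50_fold_change is not None else "-"
        lines.append(
            f"{r.receptor}\t{r.seqnum}\t{gp}\t{r.mutation}\t{r.effect_class}\t{fold}\t{r.source}"
        )
    return "\n".join(lines) + "\n"


def result_to_dict(res: EvaluationResult) -> dict:
    return {
        "counts": {"TP": res.counts.TP, "FP": res.counts.FP, "TN": res.counts.TN, "FN": res.counts.FN},
        "precision": res.precision,
        "recall": res.recall,
        "predictive_power": res.predictive_power,
        "precision_2dp": round2(res.precision),
        "recall_2dp": round2(res.recall),
        "ledger": res.ledger,
        "untested_contacts": res.untested_contacts,
    }


__all__ = [
    "MutagenesisRecord",
    "EvaluationCounts",
    "EvaluationResult",
    "precision",
    "recall",
    "predictive_power",
    "round2",
    "top_half_residues",
    "evaluate_complex",
    "read_mutagenesis_tsv",
    "records_to_tsv",
    "result_to_dict",
    "DEFAULT_FOLD_CHANGE_THRESHOLD",
]
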