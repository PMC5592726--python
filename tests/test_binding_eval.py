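"""Confusion-matrix evaluation, precision/recall, and the top-half rule."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpcreval.binding_eval import (
    EvaluationCounts,
    MutagenesisRecord,
    evaluate_complex,
    precision,
    predictive_power,
    read_mutagenesis_tsv,
    recall,
    records_to_tsv,
    round2,
    top_half_residues,
)
from gpcreval.contacts import LigandContact
from gpcreval.errors import ValidationError
from gpcreval.structure_model import Atom, Residue, StructureModel, bundle_axis


def _contact(seqnum, labels=("hbond",)):
    return LigandContact(rid=("A", seqnum, ""), resname="SER",
                         min_distance=3.0, labels=frozenset(labels))


def _rec(seqnum, effect):
    return MutagenesisRecord(receptor="r", seqnum=seqnum, mutation=f"X{seqnum}A",
                             effect_class=effect)


def _top(*seqnums):
    return {("A", sn, "") for sn in seqnums}


class TestMetrics:
    @pytest.mark.parametrize("tp,fp,expected", [(3, 1, 0.75), (1, 1, 0.50), (0, 0, 0.0)])
    def test_precision(self, tp, fp, expected):
        assert precision(EvaluationCounts(TP=tp, FP=fp, TN=0, FN=0)) == pytest.approx(expected)

    @pytest.mark.parametrize("tp,fn,expected", [(2, 1, 2 / 3), (3, 0, 1.0), (0, 3, 0.0)])
    def test_recall(self, tp, fn, expected):
        assert recall(EvaluationCounts(TP=tp, FP=0, TN=0, FN=fn)) == pytest.approx(expected)

    def test_recall_displays_as_067(self):
        assert round2(recall(EvaluationCounts(TP=2, FP=0, TN=0, FN=1))) == 0.67

    def test_predictive_power(self):
        assert predictive_power(EvaluationCounts(TP=1, FP=1, TN=1, FN=1)) == pytest.approx(50.0)
        assert predictive_power(EvaluationCounts(TP=2, FP=0, TN=3, FN=0)) == pytest.approx(100.0)

    def test_predictive_power_zero_total_rejected(self):
        with pytest.raises(ValidationError):
            predictive_power(EvaluationCounts(TP=0, FP=0, TN=0, FN=0))

    @given(tp=st.integers(0, 50), fp=st.integers(0, 50), fn=st.integers(0, 50))
    @settings(max_examples=60, derandomize=True)
    def test_metrics_in_range_and_monotone_in_tp(self, tp, fp, fn):
        c = EvaluationCounts(TP=tp, FP=fp, TN=0, FN=fn)
        assert 0.0 <= precision(c) <= 1.0
        assert 0.0 <= recall(c) <= 1.0
        c_up = EvaluationCounts(TP=tp + 1, FP=fp, TN=0, FN=fn)
        assert precision(c_up) >= precision(c)
        assert recall(c_up) >= recall(c)


class TestTopHalf:
    @staticmethod
    def _stack(zs):
        residues = [
            Residue(chain="A", seqnum=i + 1, icode="", name3="ALA",
                    atoms=[Atom(serial=1, name="CA", element="C", coords=(0, 0, z))])
            for i, z in enumerate(zs)
        ]
        return StructureModel(id="stack", residues=residues)

    def test_projection_filter_with_tie_included(self):
        s = self._stack([-5.0, 0.0, 5.0])
        axis = np.array([0.0, 0.0, 1.0])
        centroid = np.array([0.0, 0.0, 0.0])
        got = top_half_residues(s, axis, centroid)
        assert got == _top(2, 3)

    def test_matches_direct_coordinate_filter_on_bundle(self, default_complex):
        structure, _, _ = default_complex
        axis, centroid = bundle_axis(structure, {r.rid for r in structure.residues})
        got = top_half_residues(structure, axis, centroid)
        want = {r.rid for r in structure.residues
                if (r.ca.xyz - centroid) @ axis >= 0}
        assert got == want

    def test_residue_without_ca_excluded(self):
        s = self._stack([1.0, 2.0])
        s.residues[0].atoms = [Atom(serial=1, name="CB", element="C", coords=(0, 0, 1))]
        got = top_half_residues(s, np.array([0, 0, 1.0]), np.zeros(3))
        assert got == _top(2)


class TestEvaluateComplex:
    def test_all_affected_contacted_one_false_positive(self):
        # every affected residue predicted, exactly one no-effect residue
        # also predicted: FN=0, FP=1
        contacts = [_contact(1), _contact(2), _contact(3), _contact(4)]
        records = [_rec(1, "affects_response"), _rec(2, "affects_response"),
                   _rec(3, "affects_response"), _rec(4, "no_effect")]
        res = evaluate_complex(contacts, records, _top(1, 2, 3, 4))
        assert res.counts.as_tuple() == (3, 1, 0, 0)
        assert res.precision == pytest.approx(0.75)
        assert res.recall == pytest.approx(1.0)

    def test_empty_contacts_all_affected_missed(self):
        records = [_rec(i, "affects_response") for i in (1, 2, 3)]
        res = evaluate_complex([], records, _top(1, 2, 3))
        assert res.counts.as_tuple() == (0, 0, 0, 3)
        assert res.recall == 0.0

    def test_chemical_filter_gates_prediction(self):
        contacts = [LigandContact(rid=("A", 1, ""), resname="ALA",
                                  min_distance=5.0, labels=frozenset())]
        records = [_rec(1, "affects_response")]
        strict = evaluate_complex(contacts, records, _top(1), require_chemical=True)
        loose = evaluate_complex(contacts, records, _top(1), require_chemical=False)
        assert strict.counts.FN == 1 and strict.counts.TP == 0
        assert loose.counts.TP == 1

    def test_bottom_half_records_excluded(self):
        records = [_rec(1, "affects_response"), _rec(2, "no_effect")]
        res = evaluate_complex([_contact(1)], records, _top(1))
        assert res.counts.as_tuple() == (1, 0, 0, 0)

    def test_untested_contacts_reported_not_counted(self):
        records = [_rec(1, "affects_response")]
        res = evaluate_complex([_contact(1), _contact(9)], records, _top(1, 9))
        assert res.counts.as_tuple() == (1, 0, 0, 0)
        assert res.untested_contacts == [9]

    def test_mixed_mutations_collapse_to_affects(self):
        records = [_rec(1, "no_effect"),
                   MutagenesisRecord(receptor="r", seqnum=1, mutation="X1G",
                                     effect_class="affects_response")]
        res = evaluate_complex([_contact(1)], records, _top(1))
        assert res.counts.as_tuple() == (1, 0, 0, 0)

    def test_unknown_residue_rejected_with_listing(self):
        with pytest.raises(ValidationError, match="99"):
            evaluate_complex([], [_rec(99, "no_effect")], _top(1), known_residues={1, 2})

    def test_counts_invariants_on_ledger(self):
        records = [_rec(1, "affects_response"), _rec(2, "no_effect"),
                   _rec(3, "affects_response"), _rec(4, "no_effect")]
        res = evaluate_complex([_contact(1), _contact(2)], records, _top(1, 2, 3, 4))
        c = res.counts
        n_affected = sum(1 for e in res.ledger if e["effect"] == "affects_response")
        assert c.TP + c.FN == n_affected
        assert c.total == len(res.ledger) == 4


class TestMutagenesisIO:
    TSV = (
        "receptor\tresidue_seqnum\tgeneric_position\tmutation\teffect\tec50_fold\tsource\n"
        "r1\t24\t1.50\tN24A\taffects_response\t12.5\tlab\n"
        "r1\t55\t2.50\tR55A\t-\tabolished\tlab\n"
        "r1\t60\t-\tL60A\t-\t1.2\tlab\n"
    )

    def test_roundtrip_and_fold_change_classing(self):
        records = read_mutagenesis_tsv(io.StringIO(self.TSV))
        assert [r.effect_class for r in records] == [
            "affects_response", "affects_response", "no_effect"
        ]
        text = records_to_tsv(records)
        again = read_mutagenesis_tsv(io.StringIO(text))
        assert [(r.seqnum, r.effect_class) for r in again] == [
            (r.seqnum, r.effect_class) for r in records
        ]

    def test_duplicate_mutation_rejected(self):
        bad = self.TSV + "r1\t24\t1.50\tN24A\tno_effect\t-\tlab\n"
        with pytest.raises(ValidationError):
            read_mutagenesis_tsv(io.StringIO(bad))
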