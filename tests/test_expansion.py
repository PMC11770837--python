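"""Candidate enumeration, pair prediction, isa verification, store diffing,
stratified review sampling, and the expansion estimate."""

import numpy as np
import pytest

from semrelclass.expansion import (
    Candidate,
    HierarchyOracle,
    PredicationRecord,
    diff_with_store,
    enumerate_candidates,
    estimate_expansion,
    predict_pair,
    stratified_sample,
    verify_isa,
)
from semrelclass.schema import (
    ConstraintTable,
    EntityMention,
    N_LABELS,
    POSITIVE_LABELS,
    RelationLabel,
    SentenceRecord,
)
from semrelclass.thresholds import ThresholdTable

from conftest import mention

L = RelationLabel


def sentence_with(types_a, types_b):
    a = EntityMention("alpha", (0, 5), "CA", "alpha", tuple(types_a),
                      tuple("G" for _ in types_a))
    b = EntityMention("beta", (6, 10), "CB", "beta", tuple(types_b),
                      tuple("G" for _ in types_b))
    return SentenceRecord("D1", "S1", "alpha beta", (a, b))


class TestEnumerateCandidates:
    def test_two_by_three_types_give_six(self):
        sent = sentence_with(["T1", "T2"], ["T3", "T4", "T5"])
        rows = frozenset(
            (s, L.causes, o) for s in ("T1", "T2") for o in ("T3", "T4", "T5")
        )
        got = enumerate_candidates(sent, ConstraintTable(rows))
        forward = [c for c in got if c.subject.concept_id == "CA"]
        assert len(forward) == 6

    def test_nothing_licensed_gives_none(self):
        sent = sentence_with(["T1"], ["T2"])
        assert enumerate_candidates(sent, ConstraintTable(frozenset())) == []

    def test_three_entities_six_ordered_pairs(self):
        ents = tuple(mention(f"e{i}", 3 * i, f"C{i}", ("T1",)) for i in range(3))
        sent = SentenceRecord("D", "S", "e0 e1 e2", ents)
        table = ConstraintTable(frozenset({("T1", L.coexists_with, "T1")}))
        got = enumerate_candidates(sent, table)
        pairs = {(c.subject.concept_id, c.object.concept_id) for c in got}
        assert len(pairs) == 6

    def test_count_equals_licensed_type_product(self, rng):
        types = [f"T{i}" for i in range(5)]
        for _ in range(20):
            rows = frozenset(
                (types[rng.integers(5)], L.causes, types[rng.integers(5)])
                for _ in range(rng.integers(1, 10))
            )
            table = ConstraintTable(rows)
            ta = [types[i] for i in rng.choice(5, rng.integers(1, 4), replace=False)]
            tb = [types[i] for i in rng.choice(5, rng.integers(1, 4), replace=False)]
            sent = sentence_with(ta, tb)
            got = enumerate_candidates(sent, table)
            for subj_types, obj_types, subj_id in ((ta, tb, "CA"), (tb, ta, "CB")):
                brute = sum(
                    1
                    for s in subj_types
                    for o in obj_types
                    if any(r[0] == s and r[2] == o for r in rows)
                )
                assert sum(1 for c in got if c.subject.concept_id == subj_id) == brute


def one_hot_scorer(label_for_text):
    def scorer(samples):
        out = np.full((len(samples), N_LABELS), 0.001)
        for i, s in enumerate(samples):
            out[i, label_for_text(s).index] = 0.9
        return out
    return scorer


class TestPredictPair:
    def _candidates(self):
        sent = sentence_with(["T1", "T2"], ["T3"])
        a, b = sent.entities
        return [
            Candidate(sent, a, b, st, "T3") for st in ("T1", "T2")
        ]

    def test_single_candidate_above_threshold(self):
        cands = self._candidates()[:1]
        rec = predict_pair(cands, one_hot_scorer(lambda s: L.causes),
                           ThresholdTable.uniform())
        assert rec is not None and rec.predicate is L.causes
        assert rec.probability == pytest.approx(0.9)
        assert rec.subject_type == "T1"

    def test_all_below_threshold_gives_none(self):
        cands = self._candidates()
        rec = predict_pair(cands, one_hot_scorer(lambda s: L.no_rel),
                           ThresholdTable.uniform())
        assert rec is None

    def test_highest_eligible_probability_wins(self):
        cands = self._candidates()
        def scorer(samples):
            out = np.full((len(samples), N_LABELS), 0.001)
            out[0, L.causes.index] = 0.7
            out[1, L.treats.index] = 0.8
            return out
        rec = predict_pair(cands, scorer, ThresholdTable.uniform())
        assert rec.predicate is L.treats and rec.probability == pytest.approx(0.8)
        assert rec.subject_type == "T2"

    def test_strict_mode_restricts_to_licensed_predicates(self):
        cands = self._candidates()
        table = ConstraintTable(frozenset({("T1", L.causes, "T3"),
                                           ("T2", L.causes, "T3")}))
        def scorer(samples):
            out = np.full((len(samples), N_LABELS), 0.001)
            out[:, L.treats.index] = 0.9   # unlicensed
            out[:, L.causes.index] = 0.6   # licensed
            return out
        rec = predict_pair(cands, scorer, ThresholdTable.uniform(),
                           constraint_table=table)
        assert rec.predicate is L.causes

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            predict_pair([], one_hot_scorer(lambda s: L.causes),
                         ThresholdTable.uniform())


def record(pred=L.causes, subj="CA", obj="CB", doc="D1", sent="S1", p=0.9,
           st="T1", ot="T2"):
    return PredicationRecord(doc, sent, subj, subj, st, pred, obj, obj, ot, p)


class TestVerifyIsa:
    def _oracle(self):
        return HierarchyOracle([("CA", "CM"), ("CM", "CB")])

    def test_descendant_kept(self):
        recs = verify_isa([record(L.isa)], self._oracle())
        assert len(recs) == 1

    def test_unrelated_dropped(self):
        recs = verify_isa([record(L.isa, subj="CX", obj="CY")], self._oracle())
        assert recs == []

    def test_non_isa_pass_through(self):
        batch = [record(L.causes, subj="CX", obj="CY"), record(L.isa, subj="CX", obj="CY"),
                 record(L.treats, subj="CQ", obj="CR")]
        recs = verify_isa(batch, self._oracle())
        assert [r.predicate for r in recs] == [L.causes, L.treats]

    def test_direction_is_configurable(self):
        rec = record(L.isa, subj="CB", obj="CA")  # object below subject
        assert verify_isa([rec], self._oracle()) == []
        assert verify_isa([rec], self._oracle(), subject_below_object=False) == [rec]

    def test_missing_oracle_skips_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            recs = verify_isa([record(L.isa, subj="CX", obj="CY")], None)
        assert len(recs) == 1

    def test_hierarchy_transitive_and_irreflexive(self):
        o = self._oracle()
        assert o.is_descendant("CA", "CB")      # two hops
        assert not o.is_descendant("CB", "CA")  # wrong direction
        assert not o.is_descendant("CA", "CA")  # irreflexive without self-edge
        selfy = HierarchyOracle([("CZ", "CZ")])
        assert selfy.is_descendant("CZ", "CZ")


class TestDiffWithStore:
    def test_empty_store_all_new(self):
        new, shared, store_only = diff_with_store([record()], set())
        assert len(new) == 1 and not shared and not store_only

    def test_identical_row_shared(self):
        r = record()
        new, shared, store_only = diff_with_store([r], {r.key})
        assert not new and len(shared) == 1 and not store_only

    def test_swapped_bidirectional_arguments_shared(self):
        r = record(L.associated_with, subj="CA", obj="CB")
        swapped = ("D1", "S1", "CB", "associated_with", "CA")
        new, shared, _ = diff_with_store([r], {swapped})
        assert not new and len(shared) == 1

    def test_inverse_predicate_shared(self):
        r = record(L.part_of, subj="CA", obj="CB")
        inv = ("D1", "S1", "CB", "location_of", "CA")
        new, shared, _ = diff_with_store([r], {inv})
        assert not new and len(shared) == 1

    def test_partitions_disjoint_and_exhaustive(self, rng):
        labels = [lab.name for lab in POSITIVE_LABELS]
        for _ in range(10):
            recs = [
                record(L.from_name(labels[rng.integers(len(labels))]),
                       subj=f"C{rng.integers(4)}", obj=f"C{rng.integers(4) + 4}",
                       sent=f"S{rng.integers(3)}")
                for _ in range(int(rng.integers(1, 12)))
            ]
            store = {
                (f"D1", f"S{rng.integers(3)}", f"C{rng.integers(4)}",
                 labels[rng.integers(len(labels))], f"C{rng.integers(4) + 4}")
                for _ in range(int(rng.integers(0, 8)))
            }
            new, shared, store_only = diff_with_store(recs, store)
            from semrelclass.evaluation import canonical_relation_key as canon
            n_keys = {canon(r.key) for r in new}
            s_keys = {canon(r.key) for r in shared}
            o_keys = {canon(k) for k in store_only}
            assert not (n_keys & s_keys) and not (n_keys & o_keys) and not (s_keys & o_keys)
            assert s_keys | o_keys == {canon(k) for k in store}


class TestStratifiedSample:
    def _records(self, per_label):
        out = []
        for lab in POSITIVE_LABELS:
            for i in range(per_label):
                out.append(record(lab, subj=f"C{i}", obj=f"X{i}", sent=f"S{i}"))
        return out

    def test_full_sample_is_506(self):
        sample = stratified_sample(self._records(30), per_category=23, seed=1)
        assert len(sample) == 506

    def test_sparse_category_exhausted(self):
        recs = [record(L.causes, subj=f"C{i}", obj=f"X{i}") for i in range(5)]
        assert len(stratified_sample(recs, per_category=23, seed=0)) == 5

    def test_deterministic_under_seed(self):
        recs = self._records(40)
        a = [r.key for r in stratified_sample(recs, seed=9)]
        b = [r.key for r in stratified_sample(recs, seed=9)]
        assert a == b


class TestEstimateExpansion:
    def test_published_headline_arithmetic(self):
        assert estimate_expansion(77_541, 0.67) == 51_952

    def test_zero_accuracy(self):
        assert estimate_expansion(12345, 0.0) == 0

    def test_round_half(self):
        assert estimate_expansion(100, 0.5) == 50

    def test_accuracy_band_enforced(self):
        with pytest.raises(ValueError):
            estimate_expansion(10, 1.5)
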