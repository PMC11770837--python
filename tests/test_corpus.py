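"""Corpus construction: splits, bidirectional expansion, negatives,
representation substitution, and marker insertion."""

import numpy as np
import pytest

from semrelclass.corpus import (
    DEFAULT_MARKERS,
    assign_splits,
    expand_bidirectional,
    generate_negatives,
    insert_markers,
    strip_markers,
    substitute_representation,
)
from semrelclass.schema import (
    ConstraintTable,
    EntityMention,
    RelationInstance,
    RelationLabel,
    SentenceRecord,
)

from conftest import mention, simple_instance


def gs_instances(n_sentences, per_sentence=2):
    out = []
    for i in range(n_sentences):
        for j in range(per_sentence):
            out.append(
                simple_instance(
                    subj=f"drug{j}", obj=f"disease{j}",
                    doc=f"D{i}", sent=f"S{i}", split="train",
                )
            )
    return out


class TestAssignSplits:
    def test_gs_sentence_counts_20_80(self):
        got = assign_splits(gs_instances(10), [], [], seed=3)
        train_keys = {i.sentence.key for i in got if i.split == "train"}
        test_keys = {i.sentence.key for i in got if i.split == "test"}
        assert len(train_keys) == 2 and len(test_keys) == 8

    def test_sentence_level_consistency(self):
        got = assign_splits(gs_instances(7, per_sentence=3), [], [], seed=0)
        by_sentence = {}
        for inst in got:
            by_sentence.setdefault(inst.sentence.key, set()).add(inst.split)
        assert all(len(splits) == 1 for splits in by_sentence.values())

    def test_acc_90_10(self):
        acc = [
            simple_instance(subj=f"a{i}", obj=f"b{i}", doc="A", sent=f"S{i}")
            for i in range(20)
        ]
        got = assign_splits([], acc, [], seed=5)
        counts = {"train": 0, "val": 0}
        for inst in got:
            counts[inst.split] += 1
        assert counts == {"train": 18, "val": 2}

    def test_empty_inputs(self):
        assert assign_splits([], [], [], seed=1) == []

    def test_invariant_under_input_permutation(self, rng):
        gs = gs_instances(9)
        shuffled = [gs[i] for i in rng.permutation(len(gs))]
        a = {(i.instance_id, i.split) for i in assign_splits(gs, [], [], seed=11)}
        b = {(i.instance_id, i.split) for i in assign_splits(shuffled, [], [], seed=11)}
        assert a == b

    def test_gs_test_sentences_never_leak_to_train(self):
        got = assign_splits(gs_instances(25), [], [], seed=2)
        test_keys = {i.sentence.key for i in got if i.split == "test"}
        for inst in got:
            if inst.sentence.key in test_keys:
                assert inst.split == "test"


class TestExpandBidirectional:
    def test_associated_with_gains_reversed_duplicate(self):
        inst = simple_instance(label=RelationLabel.associated_with)
        got = expand_bidirectional([inst], seed=0)
        assert len(got) == 2
        rev = got[1]
        assert rev.label is RelationLabel.associated_with
        assert rev.subject == inst.object and rev.object == inst.subject

    def test_location_of_reverses_to_part_of(self):
        inst = simple_instance(label=RelationLabel.location_of)
        got = expand_bidirectional([inst], seed=0)
        assert [i.label for i in got] == [RelationLabel.location_of, RelationLabel.part_of]
        assert got[1].subject == inst.object

    def test_part_of_reverses_to_location_of(self):
        inst = simple_instance(label=RelationLabel.part_of)
        got = expand_bidirectional([inst], seed=0)
        assert got[1].label is RelationLabel.location_of

    def test_ten_percent_of_interacts_with(self):
        insts = [
            simple_instance(subj=f"x{i}", obj=f"y{i}", sent=f"S{i}",
                            label=RelationLabel.interacts_with)
            for i in range(10)
        ]
        got = expand_bidirectional(insts, interacts_fraction=0.10, seed=4)
        assert len(got) == 11

    def test_count_invariant(self, rng):
        labels = [
            RelationLabel.associated_with,
            RelationLabel.location_of,
            RelationLabel.part_of,
            RelationLabel.interacts_with,
            RelationLabel.causes,
            RelationLabel.no_rel,
        ]
        for trial in range(10):
            insts = [
                simple_instance(subj=f"x{i}", obj=f"y{i}", sent=f"S{i}",
                                label=labels[rng.integers(len(labels))])
                for i in range(rng.integers(1, 40))
            ]
            counts = {lab: sum(1 for i in insts if i.label is lab) for lab in labels}
            got = expand_bidirectional(insts, seed=trial)
            expected = (
                len(insts)
                + counts[RelationLabel.associated_with]
                + counts[RelationLabel.location_of]
                + counts[RelationLabel.part_of]
                + int(np.floor(0.10 * counts[RelationLabel.interacts_with] + 0.5))
            )
            assert len(got) == expected

    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError):
            expand_bidirectional([], interacts_fraction=1.5)


class TestGenerateNegatives:
    def _sentence(self):
        a = mention("alpha", 0, "CA", ("T1",))
        b = mention("beta", 6, "CB", ("T2",))
        return SentenceRecord("D1", "S1", "alpha beta", (a, b))

    def test_conformant_pair_emitted(self):
        sent = self._sentence()
        table = ConstraintTable(frozenset({("T2", RelationLabel.causes, "T1")}))
        gold = {("D1", "S1", "CA", "causes", "CB")}
        got = generate_negatives([sent], gold, set(), table)
        assert len(got) == 1
        (neg,) = got
        assert neg.source == "neg_conformant"
        assert (neg.subject.concept_id, neg.object.concept_id) == ("CB", "CA")
        assert neg.label is RelationLabel.no_rel

    def test_extractor_fp_emitted(self):
        sent = self._sentence()
        table = ConstraintTable(frozenset())
        fp = {("D1", "S1", "CA", "treats", "CB")}
        got = generate_negatives([sent], set(), fp, table)
        assert len(got) == 1 and got[0].source == "neg_fp"

    def test_unlicensed_pair_skipped(self):
        sent = self._sentence()
        got = generate_negatives([sent], set(), set(), ConstraintTable(frozenset()))
        assert got == []

    def test_fp_takes_precedence_over_conformant(self):
        sent = self._sentence()
        table = ConstraintTable(frozenset({("T1", RelationLabel.causes, "T2")}))
        fp = {("D1", "S1", "CA", "treats", "CB")}
        got = generate_negatives([sent], set(), fp, table)
        assert len(got) == 1 and got[0].source == "neg_fp"

    def test_cap_per_sentence(self):
        ents = tuple(
            mention(f"e{i}", 3 * i, f"C{i}", ("T1",)) for i in range(4)
        )
        text = " ".join(e.surface for e in ents)
        sent = SentenceRecord("D1", "S1", text, ents)
        table = ConstraintTable(frozenset({("T1", RelationLabel.coexists_with, "T1")}))
        got = generate_negatives([sent], set(), set(), table, cap_per_sentence=5, seed=0)
        assert len(got) == 5  # out of 12 ordered pairs


class TestSubstituteRepresentation:
    def _quercetin_instance(self):
        text = (
            "Western blotting analysis indicated that quercetin induces the "
            "G0/G1 phase arrest via decreasing the levels of CDK2, cyclins E, "
            "and D proteins"
        )
        subj = EntityMention(
            "quercetin", (text.index("quercetin"), text.index("quercetin") + 9),
            "C0034392", "quercetin",
            ("Pharmacologic Substance",), ("Chemicals and Drugs",),
        )
        obj = EntityMention(
            "CDK2", (text.index("CDK2"), text.index("CDK2") + 4),
            "C1332733", "CDK2",
            ("Gene or Genome",), ("Genes and Molecular Sequences",),
        )
        sent = SentenceRecord("D", "S", text, (subj, obj))
        return RelationInstance(
            sentence=sent, subject=subj, object=obj, label=RelationLabel.inhibits
        )

    def test_semtype_substitution_worked_sentence(self):
        got = substitute_representation(self._quercetin_instance(), "semtype")
        assert got.sentence.text == (
            "Western blotting analysis indicated that Pharmacologic Substance "
            "induces the G0/G1 phase arrest via decreasing the levels of "
            "Gene or Genome, cyclins E, and D proteins"
        )
        assert got.representation == "semtype"

    def test_semgroup_substitution_worked_sentence(self):
        got = substitute_representation(self._quercetin_instance(), "semgroup")
        assert got.sentence.text == (
            "Western blotting analysis indicated that Chemicals and Drugs "
            "induces the G0/G1 phase arrest via decreasing the levels of "
            "Genes and Molecular Sequences, cyclins E, and D proteins"
        )

    def test_mention_mode_is_identity(self):
        inst = self._quercetin_instance()
        assert substitute_representation(inst, "mention") is inst

    def test_spans_recomputed_consistently(self):
        got = substitute_representation(self._quercetin_instance(), "semtype")
        for m in (got.subject, got.object):
            assert got.sentence.text[m.span[0] : m.span[1]] == m.surface

    def test_non_argument_entities_preserved(self):
        text = "aspirin alleviates headache in adults"
        s = mention("aspirin", 0, "C1", ("Pharmacologic Substance",))
        o = mention("headache", 19, "C2", ("Disease or Syndrome",))
        other = mention("adults", 31, "C3", ("Population Group",))
        sent = SentenceRecord("D", "S", text, (s, o, other))
        inst = RelationInstance(sentence=sent, subject=s, object=o,
                                label=RelationLabel.treats)
        got = substitute_representation(inst, "semtype")
        kept = [e for e in got.sentence.entities if e.concept_id == "C3"]
        assert len(kept) == 1
        assert got.sentence.text[kept[0].span[0] : kept[0].span[1]] == "adults"


class TestInsertMarkers:
    def test_simple_construction(self):
        inst = simple_instance(subj="A", verb="inhibits", obj="B")
        seq = insert_markers(inst)
        assert seq.text == "<s>A</s> inhibits <o>B</o>"
        assert seq.stripped() == "A inhibits B"
        assert seq.text[slice(*seq.subject_span)] == "<s>A</s>"
        assert seq.text[slice(*seq.object_span)] == "<o>B</o>"

    def test_identical_spans_rejected(self):
        inst = simple_instance()
        clone = EntityMention(
            inst.subject.surface, inst.subject.span, "C_other",
            inst.subject.preferred_name, inst.subject.semantic_types,
            inst.subject.semantic_groups,
        )
        sent = SentenceRecord(
            inst.sentence.doc_id, inst.sentence.sentence_id,
            inst.sentence.text, (inst.subject, clone, inst.object),
        )
        bad = RelationInstance(sentence=sent, subject=inst.subject, object=clone,
                               label=RelationLabel.treats)
        with pytest.raises(ValueError, match="identical"):
            insert_markers(bad)

    def test_nested_spans_round_trip(self):
        text = "tumor cells proliferate"
        outer = mention("tumor cells", 0, "C_o", ("Cell",))
        inner = mention("tumor", 0, "C_i", ("Neoplastic Process",))
        sent = SentenceRecord("D", "S", text, (outer, inner))
        inst = RelationInstance(sentence=sent, subject=inner, object=outer,
                                label=RelationLabel.part_of)
        seq = insert_markers(inst)
        assert seq.stripped() == text
        # markers nest: object opens first, subject closes inside
        assert seq.text.index("<o>") < seq.text.index("<s>")
        assert seq.text.index("</s>") < seq.text.index("</o>")

    def test_strip_is_identity_on_random_fixtures(self, rng):
        words = ["alpha", "beta", "gamma", "delta", "eps"]
        for _ in range(1000):
            n = int(rng.integers(3, 8))
            toks = [words[rng.integers(len(words))] for _ in range(n)]
            text = " ".join(toks)
            # choose two disjoint word spans
            i, j = sorted(rng.choice(n, size=2, replace=False).tolist())
            def span_of(k):
                start = sum(len(t) + 1 for t in toks[:k])
                return (start, start + len(toks[k]))
            si, sj = span_of(i), span_of(j)
            a = EntityMention(toks[i], si, "CA", toks[i], ("T1",), ("G1",))
            b = EntityMention(toks[j], sj, "CB", toks[j], ("T1",), ("G1",))
            sent = SentenceRecord("D", "S", text, tuple(sorted((a, b), key=lambda m: m.span)))
            inst = RelationInstance(sentence=sent, subject=a, object=b,
                                    label=RelationLabel.causes)
            assert insert_markers(inst).stripped() == text
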