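import numpy as np
import pytest

from semrelclass.schema import (
    ConstraintTable,
    EntityMention,
    RelationLabel,
    SentenceRecord,
    RelationInstance,
)


def mention(surface, start, cui="C1", types=("T1",), groups=None):
    return EntityMention(
        surface=surface,
        span=(start, start + len(surface)),
        concept_id=cui,
        preferred_name=surface,
        semantic_types=tuple(types),
        semantic_groups=tuple(groups) if groups else tuple(types),
    )


def simple_instance(
    subj="aspirin",
    verb="alleviates",
    obj="headache",
    label=RelationLabel.treats,
    subj_types=("Pharmacologic Substance",),
    obj_types=("Disease or Syndrome",),
    doc="D1",
    sent="S1",
    split="train",
):
    text = f"{subj} {verb} {obj}"
    s = mention(subj, 0, "C_subj", subj_types,
                ("Chemicals and Drugs",) if subj_types[0] == "Pharmacologic Substance" else None)
    o = mention(obj, len(subj) + len(verb) + 2, "C_obj", obj_types,
                ("Disorders",) if obj_types[0] == "Disease or Syndrome" else None)
    record = SentenceRecord(doc_id=doc, sentence_id=sent, text=text, entities=(s, o))
    return RelationInstance(
        sentence=record, subject=s, object=o, label=label, split=split
    )


@pytest.fixture
def tiny_table():
    return ConstraintTable(
        frozenset(
            {
                ("T1", RelationLabel.causes, "T2"),
                ("T1", RelationLabel.treats, "T3"),
                ("T2", RelationLabel.part_of, "T1"),
            }
        )
    )


@pytest.fixture(scope="session")
def synth_corpus_small():
    from semrelclass.synth import SynthConfig, make_corpus

    return make_corpus(SynthConfig(n_sentences=300, seed=7))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
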