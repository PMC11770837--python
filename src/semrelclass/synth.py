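"""Seeded synthetic corpora and SemMedDB-style tables.

Sentences follow the template "context SUBJECT TRIGGER OBJECT context",
where the trigger phrase determines the relation label (mirroring the
indicator-word signal rule-based extractors rely on: "induces" -> causes,
and so on).  Hard negatives are constraint-conformant entity pairs joined
by neutral verbs and labeled no_rel.  Every planted (subject type, label,
object type) combination appears in the generated constraint table, class
frequencies follow a configurable skew, and optional label noise corrupts a
fraction of planted labels last.  With zero noise a trigger-lookup oracle
achieves F1 = 1.0 — the separability guarantee behind the learnability
checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .corpus import DEFAULT_MARKERS, MarkedSequence, MarkerSet
from .evaluation import RelationKey
from .schema import (
    ConstraintTable,
    EntityMention,
    N_LABELS,
    RelationInstance,
    RelationLabel,
    SentenceRecord,
)

__all__ = [
    "SynthConfig",
    "SynthCorpus",
    "SemmedTables",
    "make_corpus",
    "make_semmeddb_tables",
    "TriggerOracleClassifier",
    "DEFAULT_TRIGGERS",
    "DEFAULT_CONSTRAINTS",
]

# trigger phrases per label; indicator-style causal verbs for the causal
# types, conventional patterns for the rest.  Disjoint from context vocab.
DEFAULT_TRIGGERS: dict[RelationLabel, tuple[str, ...]] = {
    RelationLabel.causes: ("induces", "leads to", "provokes"),
    RelationLabel.treats: ("alleviates", "is prescribed for"),
    RelationLabel.inhibits: ("suppresses", "downregulates"),
    RelationLabel.stimulates: ("upregulates", "potentiates"),
    RelationLabel.predisposes: ("predisposes to", "raises susceptibility to"),
    RelationLabel.coexists_with: ("co-occurs with", "accompanies"),
    RelationLabel.isa: ("is a subtype of", "is classified as"),
    RelationLabel.part_of: ("is a component of", "belongs to"),
    RelationLabel.associated_with: ("correlates with",),
    RelationLabel.interacts_with: ("binds",),
    RelationLabel.location_of: ("harbors",),
    RelationLabel.prevents: ("protects against",),
    RelationLabel.affects: ("modulates",),
    RelationLabel.augments: ("amplifies",),
    RelationLabel.administered_to: ("is infused into",),
    RelationLabel.diagnoses: ("confirms",),
    RelationLabel.disrupts: ("destabilizes",),
    RelationLabel.compared_with: ("is benchmarked against",),
    RelationLabel.precedes: ("antedates",),
    RelationLabel.process_of: ("unfolds within",),
    RelationLabel.produces: ("secretes",),
    RelationLabel.uses: ("employs",),
}

NEUTRAL_VERBS = ("was measured alongside", "was recorded with", "was documented near")

# (subject type, label, object type) combinations for the planted relations
DEFAULT_CONSTRAINTS: dict[RelationLabel, tuple[tuple[str, str], ...]] = {
    RelationLabel.causes: (
        ("Pharmacologic Substance", "Disease or Syndrome"),
        ("Virus", "Disease or Syndrome"),
    ),
    RelationLabel.treats: (("Pharmacologic Substance", "Disease or Syndrome"),),
    RelationLabel.inhibits: (("Pharmacologic Substance", "Gene or Genome"),),
    RelationLabel.stimulates: (("Pharmacologic Substance", "Gene or Genome"),),
    RelationLabel.predisposes: (("Gene or Genome", "Disease or Syndrome"),),
    RelationLabel.coexists_with: (("Disease or Syndrome", "Disease or Syndrome"),),
    RelationLabel.isa: (("Disease or Syndrome", "Disease or Syndrome"),),
    RelationLabel.part_of: (
        ("Disease or Syndrome", "Body Part, Organ, or Organ Component"),
    ),
    RelationLabel.associated_with: (("Gene or Genome", "Disease or Syndrome"),),
    RelationLabel.interacts_with: (
        ("Pharmacologic Substance", "Pharmacologic Substance"),
    ),
    RelationLabel.location_of: (
        ("Body Part, Organ, or Organ Component", "Disease or Syndrome"),
    ),
    RelationLabel.prevents: (("Pharmacologic Substance", "Disease or Syndrome"),),
    RelationLabel.affects: (("Pathologic Function", "Cell Function"),),
    RelationLabel.augments: (("Pharmacologic Substance", "Cell Function"),),
    RelationLabel.administered_to: (("Pharmacologic Substance", "Population Group"),),
    RelationLabel.diagnoses: (("Diagnostic Procedure", "Disease or Syndrome"),),
    RelationLabel.disrupts: (("Pharmacologic Substance", "Cell Function"),),
    RelationLabel.compared_with: (
        ("Pharmacologic Substance", "Pharmacologic Substance"),
    ),
    RelationLabel.precedes: (("Disease or Syndrome", "Disease or Syndrome"),),
    RelationLabel.process_of: (("Disease or Syndrome", "Population Group"),),
    RelationLabel.produces: (
        ("Neoplastic Process", "Amino Acid, Peptide, or Protein"),
    ),
    RelationLabel.uses: (
        ("Therapeutic or Preventive Procedure", "Pharmacologic Substance"),
    ),
}

_TYPE_ABBR = {
    "Pharmacologic Substance": "phsu",
    "Disease or Syndrome": "dsyn",
    "Gene or Genome": "gngm",
    "Body Part, Organ, or Organ Component": "bpoc",
    "Virus": "virs",
    "Pathologic Function": "patf",
    "Cell Function": "celf",
    "Population Group": "popg",
    "Diagnostic Procedure": "diap",
    "Neoplastic Process": "neop",
    "Amino Acid, Peptide, or Protein": "aapp",
    "Therapeutic or Preventive Procedure": "topp",
}

_TYPE_GROUP = {
    "Pharmacologic Substance": "Chemicals and Drugs",
    "Disease or Syndrome": "Disorders",
    "Gene or Genome": "Genes and Molecular Sequences",
    "Body Part, Organ, or Organ Component": "Anatomy",
    "Virus": "Living Beings",
    "Pathologic Function": "Disorders",
    "Cell Function": "Physiology",
    "Population Group": "Living Beings",
    "Diagnostic Procedure": "Procedures",
    "Neoplastic Process": "Disorders",
    "Amino Acid, Peptide, or Protein": "Chemicals and Drugs",
    "Therapeutic or Preventive Procedure": "Procedures",
}

# context-word families; each member's synonyms are the other members
_CONTEXT_FAMILIES = (
    ("recent", "new", "current"),
    ("clinical", "preclinical", "translational"),
    ("murine", "rodent", "animal"),
    ("cohort", "population", "sample"),
    ("analyses", "experiments", "assays"),
    ("notably", "strikingly", "remarkably"),
)

_DEFAULT_LABELS = (
    RelationLabel.causes,
    RelationLabel.treats,
    RelationLabel.inhibits,
    RelationLabel.stimulates,
    RelationLabel.predisposes,
    RelationLabel.coexists_with,
    RelationLabel.isa,
    RelationLabel.part_of,
)


@dataclass(frozen=True)
class SynthConfig:
    n_sentences: int = 2000
    relation_labels: tuple[RelationLabel, ...] = _DEFAULT_LABELS
    trigger_lexicon: Mapping[RelationLabel, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_TRIGGERS)
    )
    constraint_rows: Mapping[RelationLabel, tuple[tuple[str, str], ...]] = field(
        default_factory=lambda: dict(DEFAULT_CONSTRAINTS)
    )
    concepts_per_type: int = 12
    negative_fraction: float = 0.465
    label_noise: float = 0.0
    class_skew: float = 1.0
    split_fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.negative_fraction <= 1.0:
            raise ValueError("negative_fraction must be in [0,1]")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must be in [0,1]")
        if self.class_skew <= 0:
            raise ValueError("class_skew must be positive")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split_fractions must sum to 1")
        for lab in self.relation_labels:
            if lab.is_null:
                raise ValueError("relation_labels must be non-null")
            if not self.trigger_lexicon.get(lab):
                raise ValueError(f"no trigger phrases for requested label {lab.name}")
            if not self.constraint_rows.get(lab):
                raise ValueError(f"no constraint rows for requested label {lab.name}")


@dataclass(frozen=True)
class SynthCorpus:
    instances: tuple[RelationInstance, ...]
    gold: frozenset[RelationKey]
    constraints: ConstraintTable
    synonym_lexicon: Mapping[str, tuple[str, ...]]
    type_group_map: Mapping[str, str]

    @property
    def sentences(self) -> list[SentenceRecord]:
        seen: dict[tuple[str, str], SentenceRecord] = {}
        for inst in self.instances:
            seen.setdefault(inst.sentence.key, inst.sentence)
        return list(seen.values())


def _inventory(config: SynthConfig) -> dict[str, list[tuple[str, str]]]:
    """semantic type -> [(cui, single-token name), ...]"""
    types: list[str] = []
    for lab in config.relation_labels:
        for st, ot in config.constraint_rows[lab]:
            for t in (st, ot):
                if t not in types:
                    types.append(t)
    out: dict[str, list[tuple[str, str]]] = {}
    serial = 0
    for t in types:
        abbr = _TYPE_ABBR.get(t, "".join(w[0] for w in t.split()).lower())
        out[t] = []
        for i in range(config.concepts_per_type):
            serial += 1
            out[t].append((f"C{serial:07d}", f"{abbr}{i}"))
    return out


def _class_weights(k: int, skew: float) -> np.ndarray:
    if k == 1:
        return np.array([1.0])
    w = skew ** (-np.arange(k) / (k - 1))  # max/min frequency ratio = skew
    return w / w.sum()


def _synonym_lexicon() -> dict[str, tuple[str, ...]]:
    lex: dict[str, tuple[str, ...]] = {}
    for family in _CONTEXT_FAMILIES:
        for w in family:
            lex[w] = tuple(x for x in family if x != w)
    return lex


def make_corpus(config: SynthConfig) -> SynthCorpus:
    """Generate a fully seeded synthetic corpus.

    Sentence splits are assigned at sentence level by the configured
    fractions.  Gold predications cover every positive (pre-noise)
    instance.  The returned constraint table licenses exactly the planted
    combinations, so hard negatives are conformant by construction."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    inventory = _inventory(config)
    labels = list(config.relation_labels)
    weights = _class_weights(len(labels), config.class_skew)

    rows = set()
    for lab in labels:
        for st, ot in config.constraint_rows[lab]:
            rows.add((st, lab, ot))
    constraints = ConstraintTable(frozenset(rows))

    n_neg = int(math.floor(config.negative_fraction * config.n_sentences + 0.5))
    n_pos = config.n_sentences - n_neg
    is_negative = np.zeros(config.n_sentences, dtype=bool)
    if config.n_sentences:
        is_negative[rng.choice(config.n_sentences, size=n_neg, replace=False)] = True

    instances: list[RelationInstance] = []
    gold: set[RelationKey] = set()

    # sentence-level split assignment
    n = config.n_sentences
    order = rng.permutation(n)
    f_train, f_val, _ = config.split_fractions
    n_train = int(math.floor(f_train * n))
    n_val = int(math.floor(f_val * n))
    split_of = {}
    for rank, idx in enumerate(order):
        split_of[idx] = (
            "train" if rank < n_train else "val" if rank < n_train + n_val else "test"
        )

    families = [list(f) for f in _CONTEXT_FAMILIES]

    for i in range(config.n_sentences):
        negative = bool(is_negative[i])
        if negative:
            lab = labels[int(rng.integers(len(labels)))]
            verb = NEUTRAL_VERBS[int(rng.integers(len(NEUTRAL_VERBS)))]
        else:
            lab = labels[int(rng.choice(len(labels), p=weights))]
            trigs = config.trigger_lexicon[lab]
            verb = trigs[int(rng.integers(len(trigs)))]
        st, ot = config.constraint_rows[lab][
            int(rng.integers(len(config.constraint_rows[lab])))
        ]
        subj_cui, subj_name = inventory[st][int(rng.integers(len(inventory[st])))]
        while True:
            obj_cui, obj_name = inventory[ot][int(rng.integers(len(inventory[ot])))]
            if obj_cui != subj_cui:
                break

        c = [fam[int(rng.integers(len(fam)))] for fam in families]
        prefix = f"In {c[0]} {c[1]} {c[4]} of the {c[2]} {c[3]} , "
        suffix = f" , {c[5]} ."
        subj_start = len(prefix)
        text = prefix + subj_name + " " + verb + " "
        obj_start = len(text)
        text = text + obj_name + suffix

        subj = EntityMention(
            surface=subj_name,
            span=(subj_start, subj_start + len(subj_name)),
            concept_id=subj_cui,
            preferred_name=subj_name,
            semantic_types=(st,),
            semantic_groups=(_TYPE_GROUP.get(st, st),),
        )
        obj = EntityMention(
            surface=obj_name,
            span=(obj_start, obj_start + len(obj_name)),
            concept_id=obj_cui,
            preferred_name=obj_name,
            semantic_types=(ot,),
            semantic_groups=(_TYPE_GROUP.get(ot, ot),),
        )
        sent = SentenceRecord(
            doc_id=f"D{i // 10:05d}",
            sentence_id=f"S{i:06d}",
            text=text,
            entities=tuple(sorted((subj, obj), key=lambda m: m.span)),
        )
        final_label = RelationLabel.no_rel if negative else lab
        if not negative:
            gold.add((sent.doc_id, sent.sentence_id, subj_cui, lab.name, obj_cui))
        # label noise last: corrupt the stored label, not the gold record
        if config.label_noise and rng.random() < config.label_noise:
            pool = [l for l in labels + [RelationLabel.no_rel] if l is not final_label]
            final_label = pool[int(rng.integers(len(pool)))]
        instances.append(
            RelationInstance(
                sentence=sent,
                subject=subj,
                object=obj,
                label=final_label,
                source="synthetic",
                split=split_of[i],
            )
        )

    return SynthCorpus(
        instances=tuple(instances),
        gold=frozenset(gold),
        constraints=constraints,
        synonym_lexicon=_synonym_lexicon(),
        type_group_map=dict(_TYPE_GROUP),
    )


@dataclass(frozen=True)
class SemmedTables:
    sentences: tuple[SentenceRecord, ...]
    store: frozenset[RelationKey]
    hierarchy_edges: tuple[tuple[str, str], ...]
    planted_new: frozenset[RelationKey]
    isa_violations: frozenset[RelationKey]


def make_semmeddb_tables(
    corpus: SynthCorpus,
    hold_out_fraction: float,
    seed: int = 0,
    isa_violation_fraction: float = 0.0,
) -> SemmedTables:
    """Derive SemMedDB-style inputs from a synthetic corpus.

    The predication store holds all gold predications except a seeded
    hold-out (``planted_new``) the expansion pipeline should rediscover.
    The toy hierarchy contains a subject->object edge for every gold isa
    predication except a seeded fraction, which thereby become
    hierarchy-violating isa records that isa verification must drop."""
    if not 0.0 <= hold_out_fraction <= 1.0:
        raise ValueError("hold_out_fraction must be in [0,1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))
    gold = sorted(corpus.gold)
    n_hold = int(math.floor(hold_out_fraction * len(gold) + 0.5))
    idx = set(rng.choice(len(gold), size=n_hold, replace=False).tolist()) if n_hold else set()
    planted_new = frozenset(gold[i] for i in idx)
    store = frozenset(k for i, k in enumerate(gold) if i not in idx)

    isa_keys = sorted(k for k in gold if k[3] == RelationLabel.isa.name)
    isa_pairs = sorted({(k[2], k[4]) for k in isa_keys})
    n_viol = int(math.floor(isa_violation_fraction * len(isa_pairs) + 0.5))
    viol_idx = (
        set(rng.choice(len(isa_pairs), size=n_viol, replace=False).tolist())
        if n_viol
        else set()
    )
    candidate_viol = {isa_pairs[i] for i in viol_idx}
    edges = tuple(sorted(p for p in isa_pairs if p not in candidate_viol))
    # a withheld pair can still be transitively reachable through kept
    # edges; only genuinely unreachable pairs count as violations
    from .expansion import HierarchyOracle

    oracle = HierarchyOracle(edges)
    violations = frozenset(
        k
        for k in isa_keys
        if (k[2], k[4]) in candidate_viol and not oracle.is_descendant(k[2], k[4])
    )
    return SemmedTables(
        sentences=tuple(corpus.sentences),
        store=store,
        hierarchy_edges=edges,
        planted_new=planted_new,
        isa_violations=violations,
    )


class TriggerOracleClassifier:
    """Perfect classifier for synthetic corpora: looks the trigger phrase up
    between the subject and object regions.

    Returns near-one-hot probability vectors; the label's probability is
    ``confidence`` and the rest share the remainder.  A pair whose subject
    does not precede the object, or whose connective is not a known
    trigger, is classified no_rel — which is exactly how the corpora are
    generated."""

    def __init__(
        self,
        trigger_lexicon: Mapping[RelationLabel, Sequence[str]] | None = None,
        confidence: float = 0.9,
        markers: MarkerSet = DEFAULT_MARKERS,
    ):
        lex = trigger_lexicon or DEFAULT_TRIGGERS
        self._by_trigger = {
            t: lab for lab, trigs in lex.items() for t in trigs
        }
        self.confidence = confidence
        self.markers = markers

    def label_of(self, sample: MarkedSequence) -> RelationLabel:
        s0, s1 = sample.subject_span
        o0, o1 = sample.object_span
        if s1 <= o0:
            between = sample.text[s1:o0].strip()
        else:
            return RelationLabel.no_rel
        for trig, lab in self._by_trigger.items():
            if between == trig:
                return lab
        return RelationLabel.no_rel

    def __call__(self, samples: Sequence[MarkedSequence]) -> np.ndarray:
        out = np.full((len(samples), N_LABELS), (1 - self.confidence) / (N_LABELS - 1))
        for i, s in enumerate(samples):
            out[i, self.label_of(s).index] = self.confidence
        return out
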