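"""Training-corpus construction: split assignment, bidirectional expansion,
negative generation, entity-representation substitution, and entity-marker
insertion.

The fully annotated gold source ("gs") is split at sentence level with most
of it reserved for testing (train fraction 0.20), because it is the only
source on which recall can be measured.  The accuracy-annotated sources
("acc", "acc_plus") contain only extractor output judged for correctness and
are split 90/10 into train/val.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .schema import (
    BIDIRECTIONAL_LABELS,
    INVERSE_LABELS,
    ConstraintTable,
    EntityMention,
    RelationInstance,
    RelationLabel,
    SentenceRecord,
    licensed_predicates,
)

__all__ = [
    "MarkerSet",
    "DEFAULT_MARKERS",
    "MarkedSequence",
    "assign_splits",
    "expand_bidirectional",
    "generate_negatives",
    "substitute_representation",
    "insert_markers",
    "strip_markers",
]

TripleKey = tuple[str, str, str, str, str]  # doc, sent, subj cui, pred, obj cui


@dataclass(frozen=True)
class MarkerSet:
    """The four reserved entity-marker tokens.

    ASCII-safe defaults; the set is recorded in checkpoints so any glyph
    choice round-trips.  Markers must be atomic for the tokenizer in use.
    """

    subj_open: str = "<s>"
    subj_close: str = "</s>"
    obj_open: str = "<o>"
    obj_close: str = "</o>"

    def all(self) -> tuple[str, str, str, str]:
        return (self.subj_open, self.subj_close, self.obj_open, self.obj_close)


DEFAULT_MARKERS = MarkerSet()


@dataclass(frozen=True)
class MarkedSequence:
    """A sentence with the subject and object wrapped in marker tokens.

    ``subject_span``/``object_span`` are character intervals in ``text``
    covering the marker-enclosed regions *including* the markers.  Removing
    all four markers reconstructs the (possibly substituted) sentence.
    """

    text: str
    subject_span: tuple[int, int]
    object_span: tuple[int, int]
    label: RelationLabel
    instance_id: str
    markers: MarkerSet = DEFAULT_MARKERS

    def __post_init__(self) -> None:
        for m in self.markers.all():
            if self.text.count(m) != 1:
                raise ValueError(
                    f"marked sequence must contain exactly one {m!r}: {self.text!r}"
                )
        for name, span, mo, mc in (
            ("subject", self.subject_span, self.markers.subj_open, self.markers.subj_close),
            ("object", self.object_span, self.markers.obj_open, self.markers.obj_close),
        ):
            seg = self.text[span[0] : span[1]]
            if not (seg.startswith(mo) and seg.endswith(mc)):
                raise ValueError(f"{name} span {span} does not cover its markers")

    def stripped(self) -> str:
        return strip_markers(self.text, self.markers)


def strip_markers(text: str, markers: MarkerSet = DEFAULT_MARKERS) -> str:
    for m in markers.all():
        text = text.replace(m, "")
    return text


# --- split assignment -------------------------------------------------------


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def _split_two_way(
    keys: list, frac_first: float, rng: np.random.Generator
) -> tuple[set, set]:
    """Sort-then-shuffle partition; first part gets floor(frac*n) items."""
    keys = sorted(keys)
    order = rng.permutation(len(keys))
    n_first = math.floor(frac_first * len(keys))
    first = {keys[i] for i in order[:n_first]}
    second = {keys[i] for i in order[n_first:]}
    return first, second


def assign_splits(
    gs_instances: Sequence[RelationInstance],
    acc_instances: Sequence[RelationInstance],
    acc_plus_instances: Sequence[RelationInstance],
    seed: int,
    gs_train_fraction: float = 0.20,
    acc_val_fraction: float = 0.10,
) -> list[RelationInstance]:
    """Assign train/val/test splits.

    gs instances are partitioned at *sentence* level: floor(0.20 n) sentences
    to train, the rest to test.  acc and acc_plus are partitioned at instance
    level, independently: floor(0.10 n) to val, remainder to train.  The
    partition is a sort-then-shuffle, so it is invariant under input-order
    permutation for a fixed seed.
    """
    out: list[RelationInstance] = []

    gs_keys = sorted({inst.sentence.key for inst in gs_instances})
    train_keys, _ = _split_two_way(gs_keys, gs_train_fraction, _rng(seed, 0))
    for inst in gs_instances:
        out.append(inst.with_split("train" if inst.sentence.key in train_keys else "test"))

    for stream, block in ((1, acc_instances), (2, acc_plus_instances)):
        ids = [inst.instance_id for inst in block]
        val_ids, _ = _split_two_way(ids, acc_val_fraction, _rng(seed, stream))
        for inst in block:
            out.append(inst.with_split("val" if inst.instance_id in val_ids else "train"))
    return out


# --- bidirectional expansion ------------------------------------------------


def _reversed_instance(
    inst: RelationInstance, label: RelationLabel | None = None
) -> RelationInstance:
    return replace(
        inst,
        subject=inst.object,
        object=inst.subject,
        label=label if label is not None else inst.label,
    )


def expand_bidirectional(
    instances: Sequence[RelationInstance],
    interacts_fraction: float = 0.10,
    seed: int = 0,
) -> list[RelationInstance]:
    """Add argument-reversed duplicates for symmetric and inverse predicates.

    Every ``associated_with`` instance gains a reversed duplicate with the
    same label; ``location_of``/``part_of`` gain a reversed instance with the
    *inverse* label; a seeded random fraction (default 10%, rounded to
    nearest) of ``interacts_with`` instances gain reversed duplicates.  All
    originals are retained.
    """
    if not 0.0 <= interacts_fraction <= 1.0:
        raise ValueError(f"interacts_fraction must be in [0,1]: {interacts_fraction}")
    out = list(instances)
    iw = [i for i in instances if i.label is RelationLabel.interacts_with]
    iw.sort(key=lambda i: i.instance_id)
    n_rev = int(math.floor(interacts_fraction * len(iw) + 0.5))
    chosen: set[int] = set()
    if n_rev > 0:
        rng = _rng(seed, 3)
        chosen = set(rng.choice(len(iw), size=n_rev, replace=False).tolist())
    iw_chosen = {iw[i].instance_id for i in chosen}

    for inst in instances:
        if inst.label is RelationLabel.associated_with:
            out.append(_reversed_instance(inst))
        elif inst.label in INVERSE_LABELS:
            out.append(_reversed_instance(inst, INVERSE_LABELS[inst.label]))
        elif inst.label is RelationLabel.interacts_with and inst.instance_id in iw_chosen:
            out.append(_reversed_instance(inst))
    return out


# --- negative generation ----------------------------------------------------


def generate_negatives(
    sentences: Sequence[SentenceRecord],
    gold: set[TripleKey],
    extractor_fp: set[TripleKey],
    table: ConstraintTable,
    cap_per_sentence: int | None = None,
    seed: int = 0,
    split: str = "train",
) -> list[RelationInstance]:
    """Emit no_rel instances of two kinds.

    ``neg_fp``: ordered pairs carrying an extractor triple absent from gold
    (hard negatives — they satisfied the extractor's own constraints).
    ``neg_conformant``: ordered pairs appearing in neither gold nor the
    extractor output but licensed by the ontological constraint table.
    Duplicate pairs are emitted once, ``neg_fp`` taking precedence.  An
    optional per-sentence cap is applied after a seeded shuffle.
    """
    out: list[RelationInstance] = []
    rng = _rng(seed, 4)
    for sent in sentences:
        gold_pairs = {
            (t[2], t[4]) for t in gold if (t[0], t[1]) == sent.key
        }
        fp_triples = {t for t in extractor_fp if (t[0], t[1]) == sent.key}
        fp_pairs = {(t[2], t[4]) for t in fp_triples}
        fp_not_gold_pairs = {
            (t[2], t[4]) for t in fp_triples if t not in gold
        }
        by_cui: dict[str, EntityMention] = {}
        for ent in sent.entities:
            by_cui.setdefault(ent.concept_id, ent)

        negatives: list[RelationInstance] = []
        ents = sorted(by_cui.values(), key=lambda e: e.span)
        for subj in ents:
            for obj in ents:
                if subj.concept_id == obj.concept_id:
                    continue
                pair = (subj.concept_id, obj.concept_id)
                if pair in fp_not_gold_pairs:
                    source = "neg_fp"
                elif pair in gold_pairs or pair in fp_pairs:
                    continue
                elif licensed_predicates(subj.semantic_types, obj.semantic_types, table):
                    source = "neg_conformant"
                else:
                    continue
                negatives.append(
                    RelationInstance(
                        sentence=sent,
                        subject=subj,
                        object=obj,
                        label=RelationLabel.no_rel,
                        source=source,
                        split=split,
                    )
                )
        if cap_per_sentence is not None and len(negatives) > cap_per_sentence:
            order = rng.permutation(len(negatives))
            negatives = [negatives[i] for i in sorted(order[:cap_per_sentence])]
        out.extend(negatives)
    return out


# --- representation substitution --------------------------------------------


def _contains(outer: tuple[int, int], inner: tuple[int, int]) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1]


def substitute_representation(
    instance: RelationInstance, mode: str
) -> RelationInstance:
    """Replace the two argument mentions with their primary semantic type
    (``semtype``) or group (``semgroup``) name; ``mention`` is the identity.

    Non-argument mentions keep their surface text; their spans are shifted
    to account for the replacements.  Non-argument mentions nested inside a
    replaced region are dropped (their surface no longer exists).
    """
    if mode == "mention":
        return instance
    if mode not in ("semtype", "semgroup"):
        raise ValueError(f"unknown representation mode: {mode!r}")

    subj, obj = instance.subject, instance.object
    if _contains(subj.span, obj.span) or _contains(obj.span, subj.span):
        raise ValueError("cannot substitute nested argument spans")

    def replacement(m: EntityMention) -> str:
        if mode == "semtype":
            if not m.semantic_types:
                raise ValueError(f"mention {m.concept_id} has no semantic types")
            return m.primary_type
        if not m.semantic_groups:
            raise ValueError(f"mention {m.concept_id} has no semantic groups")
        return m.primary_group

    # apply right-to-left so earlier offsets stay valid
    edits = sorted(
        [(subj, replacement(subj)), (obj, replacement(obj))],
        key=lambda e: e[0].span[0],
    )
    text = instance.sentence.text
    deltas: list[tuple[int, int, int]] = []  # (old_start, old_end, delta)
    for mention, new_surface in reversed(edits):
        s, e = mention.span
        text = text[:s] + new_surface + text[e:]
        deltas.append((s, e, len(new_surface) - (e - s)))
    deltas.reverse()

    def shift(pos: int) -> int:
        out = pos
        for s, e, d in deltas:
            if pos >= e:
                out += d
        return out

    def new_mention(m: EntityMention, new_surface: str | None) -> EntityMention:
        if new_surface is None:  # non-argument: same surface, shifted span
            ns = (shift(m.span[0]), shift(m.span[1]))
            return EntityMention(
                m.surface, ns, m.concept_id, m.preferred_name,
                m.semantic_types, m.semantic_groups,
            )
        s = shift_arg_start(m)
        return EntityMention(
            new_surface, (s, s + len(new_surface)), m.concept_id,
            m.preferred_name, m.semantic_types, m.semantic_groups,
        )

    def shift_arg_start(m: EntityMention) -> int:
        out = m.span[0]
        for s, e, d in deltas:
            if m.span[0] > s:
                out += d
        return out

    arg_surfaces = {subj: replacement(subj), obj: replacement(obj)}
    new_entities = []
    new_subj = new_obj = None
    for ent in instance.sentence.entities:
        if ent == subj:
            new_subj = new_mention(ent, arg_surfaces[subj])
            new_entities.append(new_subj)
        elif ent == obj:
            new_obj = new_mention(ent, arg_surfaces[obj])
            new_entities.append(new_obj)
        elif any(_contains(a.span, ent.span) for a in (subj, obj)):
            continue  # swallowed by a replaced argument region
        else:
            new_entities.append(new_mention(ent, None))
    assert new_subj is not None and new_obj is not None

    sentence = SentenceRecord(
        doc_id=instance.sentence.doc_id,
        sentence_id=instance.sentence.sentence_id,
        text=text,
        entities=tuple(sorted(new_entities, key=lambda m: m.span)),
    )
    return replace(
        instance,
        sentence=sentence,
        subject=new_subj,
        object=new_obj,
        representation=mode,
    )


# --- marker insertion -------------------------------------------------------


def insert_markers(
    instance: RelationInstance, markers: MarkerSet = DEFAULT_MARKERS
) -> MarkedSequence:
    """Wrap the subject region in subject markers and the object region in
    object markers.  Nested argument spans produce properly nested markers;
    partially overlapping or identical spans are a structural error.
    """
    s_span, o_span = instance.subject.span, instance.object.span
    if s_span == o_span:
        raise ValueError("subject and object spans are identical")
    lo, hi = (s_span, o_span) if s_span <= o_span else (o_span, s_span)
    disjoint = lo[1] <= hi[0]
    nested = _contains(s_span, o_span) or _contains(o_span, s_span)
    if not (disjoint or nested):
        raise ValueError(f"partially overlapping argument spans {s_span}/{o_span}")

    # events: (pos, opener?, tie-break, marker string, which, is_open)
    # at equal positions closers precede openers; among closers the inner
    # (larger start) comes first; among openers the outer (larger end) first
    events = [
        (s_span[0], 1, -s_span[1], markers.subj_open, "s", True),
        (s_span[1], 0, -s_span[0], markers.subj_close, "s", False),
        (o_span[0], 1, -o_span[1], markers.obj_open, "o", True),
        (o_span[1], 0, -o_span[0], markers.obj_close, "o", False),
    ]
    events.sort(key=lambda e: e[:3])

    text = instance.sentence.text
    pieces: list[str] = []
    positions: dict[tuple[str, bool], int] = {}
    cursor = 0
    built = 0
    for pos, _, _, marker, which, is_open in events:
        pieces.append(text[cursor:pos])
        built += pos - cursor
        positions[(which, is_open)] = built
        pieces.append(marker)
        built += len(marker)
        cursor = pos
    pieces.append(text[cursor:])
    marked = "".join(pieces)

    subj_span = (
        positions[("s", True)],
        positions[("s", False)] + len(markers.subj_close),
    )
    obj_span = (
        positions[("o", True)],
        positions[("o", False)] + len(markers.obj_close),
    )
    return MarkedSequence(
        text=marked,
        subject_span=subj_span,
        object_span=obj_span,
        label=instance.label,
        instance_id=instance.instance_id,
        markers=markers,
    )
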