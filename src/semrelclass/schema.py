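"""Label schema, entity/sentence/instance records, and the ontological
constraint table shared by every stage of the pipeline.

The label set covers 22 positive predicate types produced by rule-based
biomedical relation extraction (SemRep-style subject-predicate-object
triples) plus the null label ``no_rel`` for entity pairs that express no
in-scope relation.  Label order is alphabetical with ``no_rel`` last so
that argmax tie-breaking is reproducible everywhere.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "RelationLabel",
    "POSITIVE_LABELS",
    "BIDIRECTIONAL_LABELS",
    "INVERSE_LABELS",
    "EntityMention",
    "SentenceRecord",
    "RelationInstance",
    "ConstraintTable",
    "licensed_predicates",
    "group_of",
    "load_type_group_map",
]

_POSITIVE_NAMES = (
    "administered_to",
    "affects",
    "associated_with",
    "augments",
    "causes",
    "coexists_with",
    "compared_with",
    "diagnoses",
    "disrupts",
    "inhibits",
    "interacts_with",
    "isa",
    "location_of",
    "part_of",
    "precedes",
    "predisposes",
    "prevents",
    "process_of",
    "produces",
    "stimulates",
    "treats",
    "uses",
)


class RelationLabel(Enum):
    """The 22 in-scope predicate types plus the null label.

    ``index`` is the fixed position used for probability vectors and for
    deterministic tie-breaking: alphabetical order, ``no_rel`` at 22.
    """

    administered_to = 0
    affects = 1
    associated_with = 2
    augments = 3
    causes = 4
    coexists_with = 5
    compared_with = 6
    diagnoses = 7
    disrupts = 8
    inhibits = 9
    interacts_with = 10
    isa = 11
    location_of = 12
    part_of = 13
    precedes = 14
    predisposes = 15
    prevents = 16
    process_of = 17
    produces = 18
    stimulates = 19
    treats = 20
    uses = 21
    no_rel = 22

    @property
    def index(self) -> int:
        return self.value

    @property
    def is_null(self) -> bool:
        return self is RelationLabel.no_rel

    @classmethod
    def from_name(cls, name: str) -> "RelationLabel":
        try:
            return cls[name]
        except KeyError:
            raise ValueError(f"unknown relation label: {name!r}") from None

    @classmethod
    def ordered(cls) -> tuple["RelationLabel", ...]:
        return tuple(sorted(cls, key=lambda l: l.value))


POSITIVE_LABELS: tuple[RelationLabel, ...] = tuple(
    RelationLabel[n] for n in _POSITIVE_NAMES
)

#: Predicates whose arguments may be swapped without changing the meaning.
BIDIRECTIONAL_LABELS = frozenset(
    {RelationLabel.associated_with, RelationLabel.interacts_with}
)

#: Inverse-predicate pairs: A location_of B  <=>  B part_of A.
INVERSE_LABELS: Mapping[RelationLabel, RelationLabel] = {
    RelationLabel.location_of: RelationLabel.part_of,
    RelationLabel.part_of: RelationLabel.location_of,
}

N_LABELS = len(RelationLabel)


@dataclass(frozen=True)
class EntityMention:
    """A single concept mention inside a sentence.

    ``span`` is a 0-based half-open character interval into the owning
    sentence.  ``semantic_types`` is the ordered list of fine-grained
    ontological categories of the concept (first entry = primary type);
    ``semantic_groups`` the corresponding coarse groups.
    """

    surface: str
    span: tuple[int, int]
    concept_id: str
    preferred_name: str
    semantic_types: tuple[str, ...]
    semantic_groups: tuple[str, ...]

    def __post_init__(self) -> None:
        start, end = self.span
        if not (0 <= start < end):
            raise ValueError(f"invalid span {self.span} for {self.surface!r}")
        if not self.semantic_types:
            raise ValueError(f"mention {self.concept_id} has no semantic types")
        if not self.semantic_groups:
            raise ValueError(f"mention {self.concept_id} has no semantic groups")
        object.__setattr__(self, "span", (int(start), int(end)))
        object.__setattr__(self, "semantic_types", tuple(self.semantic_types))
        object.__setattr__(self, "semantic_groups", tuple(self.semantic_groups))

    @property
    def primary_type(self) -> str:
        return self.semantic_types[0]

    @property
    def primary_group(self) -> str:
        return self.semantic_groups[0]


def _spans_partially_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    """True if the intervals overlap without one containing the other."""
    if a == b:
        return False
    lo, hi = (a, b) if a <= b else (b, a)
    if lo[1] <= hi[0]:  # disjoint
        return False
    # overlap: fine only if one nests inside the other
    nested = (a[0] <= b[0] and b[1] <= a[1]) or (b[0] <= a[0] and a[1] <= b[1])
    return not nested


@dataclass(frozen=True)
class SentenceRecord:
    """A sentence with its pre-recognized entity mentions."""

    doc_id: str
    sentence_id: str
    text: str
    entities: tuple[EntityMention, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "entities", tuple(self.entities))
        n = len(self.text)
        for ent in self.entities:
            if ent.span[1] > n:
                raise ValueError(
                    f"entity span {ent.span} exceeds sentence length {n} "
                    f"({self.doc_id}/{self.sentence_id})"
                )
            if self.text[ent.span[0] : ent.span[1]] != ent.surface:
                raise ValueError(
                    f"surface {ent.surface!r} does not match text at {ent.span}"
                )
        for i, a in enumerate(self.entities):
            for b in self.entities[i + 1 :]:
                if _spans_partially_overlap(a.span, b.span):
                    raise ValueError(
                        f"partially overlapping entity spans {a.span} / {b.span} "
                        f"in {self.doc_id}/{self.sentence_id}"
                    )

    @property
    def key(self) -> tuple[str, str]:
        return (self.doc_id, self.sentence_id)


VALID_SOURCES = ("gs", "acc", "acc_plus", "neg_fp", "neg_conformant", "synthetic")
VALID_SPLITS = ("train", "val", "test")
VALID_REPRESENTATIONS = ("mention", "semtype", "semgroup")


@dataclass(frozen=True)
class RelationInstance:
    """One (sentence, subject, object, label) classification unit."""

    sentence: SentenceRecord
    subject: EntityMention
    object: EntityMention
    label: RelationLabel
    source: str = "synthetic"
    split: str = "train"
    representation: str = "mention"

    def __post_init__(self) -> None:
        if self.subject == self.object:
            raise ValueError("subject and object must be distinct mentions")
        if self.source not in VALID_SOURCES:
            raise ValueError(f"invalid source {self.source!r}")
        if self.split not in VALID_SPLITS:
            raise ValueError(f"invalid split {self.split!r}")
        if self.representation not in VALID_REPRESENTATIONS:
            raise ValueError(f"invalid representation {self.representation!r}")
        if self.source in ("neg_fp", "neg_conformant") and not self.label.is_null:
            raise ValueError(f"{self.source} instances must carry no_rel")

    @property
    def instance_id(self) -> str:
        s0, s1 = self.subject.span
        o0, o1 = self.object.span
        return (
            f"{self.sentence.doc_id}:{self.sentence.sentence_id}"
            f":{s0}-{s1}:{o0}-{o1}:{self.label.name}"
        )

    def with_split(self, split: str) -> "RelationInstance":
        return replace(self, split=split)


@dataclass(frozen=True)
class ConstraintTable:
    """Licensed (subject semtype, predicate, object semtype) triples.

    Lookup is exact on all three fields; no inference or closure is done.
    """

    rows: frozenset[tuple[str, RelationLabel, str]] = field(
        default_factory=frozenset
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", frozenset(self.rows))
        for row in self.rows:
            if len(row) != 3 or not isinstance(row[1], RelationLabel):
                raise ValueError(f"malformed constraint row: {row!r}")

    def predicates_for(self, subject_type: str, object_type: str) -> set[RelationLabel]:
        return {
            pred
            for (s, pred, o) in self.rows
            if s == subject_type and o == object_type
        }

    def licenses(self, subject_type: str, predicate: RelationLabel, object_type: str) -> bool:
        return (subject_type, predicate, object_type) in self.rows

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConstraintTable":
        """Read a 3-column TSV (subject_semtype, predicate, object_semtype)
        with a header row."""
        rows: set[tuple[str, RelationLabel, str]] = set()
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader, None)
            if header is None or len(header) < 3:
                raise ValueError(f"constraint table {path} lacks a 3-column header")
            for lineno, row in enumerate(reader, start=2):
                if not row or all(not c.strip() for c in row):
                    continue
                if len(row) < 3:
                    raise ValueError(f"{path}:{lineno}: expected 3 columns")
                rows.add((row[0], RelationLabel.from_name(row[1]), row[2]))
        return cls(frozenset(rows))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["subject_semtype", "predicate", "object_semtype"])
            for s, pred, o in sorted(self.rows, key=lambda r: (r[0], r[1].name, r[2])):
                writer.writerow([s, pred.name, o])


def licensed_predicates(
    subject_types: Sequence[str],
    object_types: Sequence[str],
    table: ConstraintTable,
) -> set[RelationLabel]:
    """Union of predicates licensed by the table over every (subject type,
    object type) pair.  Both lists must be non-empty; an empty result set is
    a valid outcome (the pair is unlicensed)."""
    if not subject_types:
        raise ValueError("subject_types is empty")
    if not object_types:
        raise ValueError("object_types is empty")
    out: set[RelationLabel] = set()
    for s in subject_types:
        for o in object_types:
            out |= table.predicates_for(s, o)
    return out


def group_of(semantic_type: str, type_group_map: Mapping[str, str]) -> str:
    """Coarse semantic group of a fine-grained semantic type.

    Every type maps to exactly one group; an unknown type is an error that
    names the offending type.
    """
    try:
        return type_group_map[semantic_type]
    except KeyError:
        raise KeyError(f"semantic type not in type->group map: {semantic_type!r}") from None


def load_type_group_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (semantic_type, semantic_group) with header."""
    out: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader, None)
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            if row[0] in out and out[row[0]] != row[1]:
                raise ValueError(f"{path}:{lineno}: type {row[0]!r} maps to two groups")
            out[row[0]] = row[1]
    return out


def default_type_group_map() -> dict[str, str]:
    """The type->group map shipped with the package."""
    return load_type_group_map(Path(__file__).parent / "data" / "semantic_groups.tsv")
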