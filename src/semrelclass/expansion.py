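"""Large-scale predication expansion over SemMedDB-style tables.

For every sentence: enumerate ordered entity pairs under every semantic-type
combination, keep the combinations the ontological constraint table
licenses, score each with the semantic-type entity representation, apply the
calibrated per-class thresholds, take the winning prediction per pair,
verify ``isa`` predications against a concept hierarchy, and diff the
surviving predications against an existing predication store.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, replace as _dc_replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .corpus import DEFAULT_MARKERS, MarkedSequence, MarkerSet, insert_markers, substitute_representation
from .evaluation import RelationKey, canonical_relation_key
from .schema import (
    ConstraintTable,
    EntityMention,
    POSITIVE_LABELS,
    RelationInstance,
    RelationLabel,
    SentenceRecord,
)
from .thresholds import ThresholdTable

logger = logging.getLogger(__name__)

__all__ = [
    "Candidate",
    "PredicationRecord",
    "HierarchyOracle",
    "enumerate_candidates",
    "predict_pair",
    "verify_isa",
    "diff_with_store",
    "stratified_sample",
    "estimate_expansion",
    "run_expansion",
]

#: scoring interface: marked sequences -> (n, 23) probability matrix
Scorer = Callable[[Sequence[MarkedSequence]], np.ndarray]


@dataclass(frozen=True)
class Candidate:
    """One ordered entity pair under one (subject type, object type)
    combination licensed by the constraint table."""

    sentence: SentenceRecord
    subject: EntityMention
    object: EntityMention
    subject_type: str
    object_type: str


@dataclass(frozen=True)
class PredicationRecord:
    """A proposed subject-predicate-object predication."""

    doc_id: str
    sentence_id: str
    subject_cui: str
    subject_name: str
    subject_type: str
    predicate: RelationLabel
    object_cui: str
    object_name: str
    object_type: str
    probability: float

    def __post_init__(self) -> None:
        if self.predicate.is_null:
            raise ValueError("a predication cannot carry the null label")

    @property
    def key(self) -> RelationKey:
        return (
            self.doc_id,
            self.sentence_id,
            self.subject_cui,
            self.predicate.name,
            self.object_cui,
        )


class HierarchyOracle:
    """Transitive is-descendant lookup over a parent-child edge table.

    Irreflexive unless the table contains a self-edge; the closure is
    computed by upward traversal, so cycles do not loop."""

    def __init__(self, edges: Iterable[tuple[str, str]]):
        self._parents: dict[str, set[str]] = {}
        for child, parent in edges:
            self._parents.setdefault(child, set()).add(parent)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HierarchyOracle":
        """2-column TSV (child, parent) with a header row."""
        edges = []
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh, delimiter="\t")
            next(reader, None)
            for row in reader:
                if len(row) >= 2 and row[0]:
                    edges.append((row[0], row[1]))
        return cls(edges)

    def is_descendant(self, concept_a: str, concept_b: str) -> bool:
        """True if ``concept_a`` lies below ``concept_b`` in the hierarchy."""
        seen: set[str] = set()
        stack = list(self._parents.get(concept_a, ()))
        while stack:
            node = stack.pop()
            if node == concept_b:
                return True
            if node in seen:
                continue
            seen.add(node)
            stack.extend(self._parents.get(node, ()))
        return False


def enumerate_candidates(
    sentence: SentenceRecord, table: ConstraintTable
) -> list[Candidate]:
    """All ordered pairs of distinct entities under all semantic-type
    combinations, filtered to those the constraint table licenses.

    A subject with 2 types and an object with 3, all licensed, yields 6
    candidates for that ordered pair.  Order is deterministic: entities by
    span, types as listed on the mention."""
    ents = sorted(sentence.entities, key=lambda e: (e.span, e.concept_id))
    out: list[Candidate] = []
    for subj in ents:
        for obj in ents:
            if subj == obj:
                continue
            for st in subj.semantic_types:
                for ot in obj.semantic_types:
                    if table.predicates_for(st, ot):
                        out.append(Candidate(sentence, subj, obj, st, ot))
    return out


def _with_primary_type(mention: EntityMention, semtype: str) -> EntityMention:
    """Reorder the mention's type list so ``semtype`` is primary."""
    types = (semtype,) + tuple(t for t in mention.semantic_types if t != semtype)
    return _dc_replace(mention, semantic_types=types)


def candidate_sample(candidate: Candidate, markers: MarkerSet = DEFAULT_MARKERS) -> MarkedSequence:
    """The marked, semantic-type-substituted input for one candidate."""
    subj = _with_primary_type(candidate.subject, candidate.subject_type)
    obj = _with_primary_type(candidate.object, candidate.object_type)
    entities = tuple(
        subj if e == candidate.subject else obj if e == candidate.object else e
        for e in candidate.sentence.entities
    )
    sent = SentenceRecord(
        candidate.sentence.doc_id,
        candidate.sentence.sentence_id,
        candidate.sentence.text,
        entities,
    )
    inst = RelationInstance(
        sentence=sent, subject=subj, object=obj, label=RelationLabel.no_rel,
        source="neg_conformant",
    )
    return insert_markers(substitute_representation(inst, "semtype"), markers)


def _decide(
    probs: np.ndarray,
    thresholds: ThresholdTable,
    allowed: set[RelationLabel] | None,
) -> tuple[RelationLabel, float] | None:
    best: tuple[RelationLabel, float] | None = None
    for lab in POSITIVE_LABELS:  # index order = earlier-label tie-break
        if allowed is not None and lab not in allowed:
            continue
        p = float(probs[lab.index])
        if p >= thresholds[lab] and (best is None or p > best[1]):
            best = (lab, p)
    return best


def predict_pair(
    candidates: Sequence[Candidate],
    scorer: Scorer,
    thresholds: ThresholdTable,
    markers: MarkerSet = DEFAULT_MARKERS,
    constraint_table: ConstraintTable | None = None,
) -> PredicationRecord | None:
    """Score every semantic-type combination of one ordered pair and keep
    the best threshold-eligible prediction.

    Each candidate is scored with the semantic-type-substituted
    representation; across candidates the (label, probability) with maximal
    eligible probability wins, ties broken toward the earlier label order
    and then the earlier candidate.  If every candidate resolves to the
    null label the pair yields nothing.  Supplying ``constraint_table``
    activates strict mode: predictions are restricted to predicates the
    table licenses for the candidate's type pair."""
    if not candidates:
        raise ValueError("predict_pair requires at least one candidate")
    samples = [candidate_sample(c, markers) for c in candidates]
    probs = scorer(samples)
    best: tuple[float, PredicationRecord] | None = None
    for cand, p in zip(candidates, probs):
        allowed = None
        if constraint_table is not None:
            allowed = constraint_table.predicates_for(cand.subject_type, cand.object_type)
        decision = _decide(np.asarray(p), thresholds, allowed)
        if decision is None:
            continue
        label, prob = decision
        if best is None or prob > best[0]:
            best = (
                prob,
                PredicationRecord(
                    doc_id=cand.sentence.doc_id,
                    sentence_id=cand.sentence.sentence_id,
                    subject_cui=cand.subject.concept_id,
                    subject_name=cand.subject.preferred_name,
                    subject_type=cand.subject_type,
                    predicate=label,
                    object_cui=cand.object.concept_id,
                    object_name=cand.object.preferred_name,
                    object_type=cand.object_type,
                    probability=prob,
                ),
            )
    return best[1] if best else None


def verify_isa(
    records: Sequence[PredicationRecord],
    oracle: HierarchyOracle | None,
    subject_below_object: bool = True,
) -> list[PredicationRecord]:
    """Keep an ``isa`` predication only if its subject is a descendant of
    its object in the concept hierarchy (the conventional reading of
    "X isa Y"; flip ``subject_below_object`` for the opposite direction).
    Non-isa records pass through.  Without an oracle, verification is
    skipped with a warning."""
    if oracle is None:
        logger.warning("no concept hierarchy supplied; skipping isa verification")
        return list(records)
    out = []
    for rec in records:
        if rec.predicate is RelationLabel.isa:
            lo, hi = rec.subject_cui, rec.object_cui
            if not subject_below_object:
                lo, hi = hi, lo
            if not oracle.is_descendant(lo, hi):
                continue
        out.append(rec)
    return out


def dedup_records(records: Sequence[PredicationRecord]) -> list[PredicationRecord]:
    """Deduplicate by canonical key, keeping the highest probability."""
    best: dict[RelationKey, PredicationRecord] = {}
    for rec in records:
        k = canonical_relation_key(rec.key)
        if k not in best or rec.probability > best[k].probability:
            best[k] = rec
    return [best[k] for k in sorted(best)]


def diff_with_store(
    records: Sequence[PredicationRecord], store: set[RelationKey]
) -> tuple[list[PredicationRecord], list[PredicationRecord], set[RelationKey]]:
    """Partition into (new, shared, store_only) by canonical key; symmetric
    predicates compare under argument swap and the inverse pair under its
    inverse map."""
    canon_store = {canonical_relation_key(k): k for k in store}
    new: list[PredicationRecord] = []
    shared: list[PredicationRecord] = []
    matched: set[RelationKey] = set()
    for rec in dedup_records(records):
        k = canonical_relation_key(rec.key)
        if k in canon_store:
            shared.append(rec)
            matched.add(k)
        else:
            new.append(rec)
    store_only = {orig for canon, orig in canon_store.items() if canon not in matched}
    return new, shared, store_only


def stratified_sample(
    new: Sequence[PredicationRecord], per_category: int = 23, seed: int = 0
) -> list[PredicationRecord]:
    """Up to ``per_category`` records drawn uniformly without replacement
    for each predicate; deterministic under the seed."""
    by_pred: dict[RelationLabel, list[PredicationRecord]] = {}
    for rec in new:
        by_pred.setdefault(rec.predicate, []).append(rec)
    out: list[PredicationRecord] = []
    for lab in POSITIVE_LABELS:
        pool = sorted(by_pred.get(lab, []), key=lambda r: r.key)
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), lab.index]))
        if len(pool) <= per_category:
            out.extend(pool)
        else:
            idx = rng.choice(len(pool), size=per_category, replace=False)
            out.extend(pool[i] for i in sorted(idx))
    return out


def estimate_expansion(new_count: int, accuracy: float) -> int:
    """Estimated count of correct new predications: round(new * accuracy)."""
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError(f"accuracy must be in [0,1]: {accuracy}")
    return int(math.floor(new_count * accuracy + 0.5))


def run_expansion(
    sentences: Sequence[SentenceRecord],
    scorer: Scorer,
    thresholds: ThresholdTable,
    table: ConstraintTable,
    store: set[RelationKey],
    hierarchy: HierarchyOracle | None = None,
    markers: MarkerSet = DEFAULT_MARKERS,
    strict: bool = False,
) -> dict:
    """End-to-end expansion over a sentence collection.

    Returns a dict with ``new``, ``shared`` (PredicationRecord lists),
    ``store_only`` (keys), and per-category counts."""
    records: list[PredicationRecord] = []
    n_candidates = 0
    for sent in sentences:
        if len(sent.entities) < 2:
            continue
        cands = enumerate_candidates(sent, table)
        n_candidates += len(cands)
        by_pair: dict[tuple[str, str], list[Candidate]] = {}
        for c in cands:
            by_pair.setdefault((c.subject.concept_id, c.object.concept_id), []).append(c)
        for pair_cands in by_pair.values():
            rec = predict_pair(
                pair_cands, scorer, thresholds, markers,
                constraint_table=table if strict else None,
            )
            if rec is not None:
                records.append(rec)
    records = verify_isa(records, hierarchy)
    new, shared, store_only = diff_with_store(records, store)
    per_cat = {
        lab.name: {
            "new": sum(1 for r in new if r.predicate is lab),
            "shared": sum(1 for r in shared if r.predicate is lab),
            "store_only": sum(1 for k in store_only if k[3] == lab.name),
        }
        for lab in POSITIVE_LABELS
    }
    return {
        "candidates": n_candidates,
        "new": new,
        "shared": shared,
        "store_only": store_only,
        "per_category": per_cat,
    }
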