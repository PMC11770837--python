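"""File-format dialects: instance JSONL and the TSV tables consumed by the
expansion pipeline.  Every module reads and writes through this layer.

Instance JSONL: one object per line with fields ``doc_id``, ``sentence_id``,
``text``, ``subject``/``object`` (``span``, ``cui``, ``name``, ``semtypes``,
``semgroups``), ``label``, ``source``, ``split``, ``representation``, and an
optional ``other_entities`` list preserving non-argument mentions so the
round trip is lossless.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .schema import (
    EntityMention,
    RelationInstance,
    RelationLabel,
    SentenceRecord,
)

__all__ = [
    "read_instances",
    "write_instances",
    "read_sentences_tsv",
    "read_entities_tsv",
    "write_sentences_tsv",
    "write_entities_tsv",
]


def _mention_to_obj(m: EntityMention) -> dict:
    return {
        "span": list(m.span),
        "cui": m.concept_id,
        "name": m.preferred_name,
        "surface": m.surface,
        "semtypes": list(m.semantic_types),
        "semgroups": list(m.semantic_groups),
    }


def _mention_from_obj(obj: dict, text: str) -> EntityMention:
    span = tuple(obj["span"])
    surface = obj.get("surface", text[span[0] : span[1]])
    return EntityMention(
        surface=surface,
        span=span,  # type: ignore[arg-type]
        concept_id=obj["cui"],
        preferred_name=obj["name"],
        semantic_types=tuple(obj["semtypes"]),
        semantic_groups=tuple(obj["semgroups"]),
    )


def write_instances(instances: Iterable[RelationInstance], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for inst in instances:
            others = [
                e
                for e in inst.sentence.entities
                if e not in (inst.subject, inst.object)
            ]
            obj = {
                "doc_id": inst.sentence.doc_id,
                "sentence_id": inst.sentence.sentence_id,
                "text": inst.sentence.text,
                "subject": _mention_to_obj(inst.subject),
                "object": _mention_to_obj(inst.object),
                "label": inst.label.name,
                "source": inst.source,
                "split": inst.split,
                "representation": inst.representation,
            }
            if others:
                obj["other_entities"] = [_mention_to_obj(e) for e in others]
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def read_instances(path: str | Path) -> list[RelationInstance]:
    """Parse instance JSONL; a malformed line raises with its line number."""
    out: list[RelationInstance] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                text = obj["text"]
                subject = _mention_from_obj(obj["subject"], text)
                object_ = _mention_from_obj(obj["object"], text)
                others = tuple(
                    _mention_from_obj(e, text)
                    for e in obj.get("other_entities", [])
                )
                entities = tuple(
                    sorted({subject, object_, *others}, key=lambda m: m.span)
                )
                sentence = SentenceRecord(
                    doc_id=obj["doc_id"],
                    sentence_id=obj["sentence_id"],
                    text=text,
                    entities=entities,
                )
                inst = RelationInstance(
                    sentence=sentence,
                    subject=subject,
                    object=object_,
                    label=RelationLabel.from_name(obj["label"]),
                    source=obj.get("source", "synthetic"),
                    split=obj.get("split", "train"),
                    representation=obj.get("representation", "mention"),
                )
            except (KeyError, ValueError, json.JSONDecodeError) as exc:
                raise ValueError(f"{path}:{lineno}: invalid instance record: {exc}") from exc
            out.append(inst)
    return out


# --- SemMedDB-style TSV tables (sentences / entities) -----------------------

_SENT_COLS = ["doc_id", "sentence_id", "text"]
_ENT_COLS = ["doc_id", "sentence_id", "start", "end", "cui", "name", "semtypes"]


def write_sentences_tsv(sentences: Sequence[SentenceRecord], path: str | Path) -> None:
    pd.DataFrame(
        [[s.doc_id, s.sentence_id, s.text] for s in sentences], columns=_SENT_COLS
    ).to_csv(path, sep="\t", index=False)


def write_entities_tsv(sentences: Sequence[SentenceRecord], path: str | Path) -> None:
    rows = []
    for s in sentences:
        for e in s.entities:
            rows.append(
                [
                    s.doc_id,
                    s.sentence_id,
                    e.span[0],
                    e.span[1],
                    e.concept_id,
                    e.preferred_name,
                    "|".join(e.semantic_types),
                ]
            )
    pd.DataFrame(rows, columns=_ENT_COLS).to_csv(path, sep="\t", index=False)


def read_sentences_tsv(
    sentences_path: str | Path,
    entities_path: str | Path,
    type_group_map: dict[str, str] | None = None,
) -> list[SentenceRecord]:
    """Join a sentences TSV with an entities TSV into SentenceRecords.

    Semantic groups are derived from the pipe-separated semtypes column via
    ``type_group_map``; types missing from the map fall back to the type
    name itself so user tables need not ship a complete map.
    """
    sents = pd.read_csv(sentences_path, sep="\t", dtype=str)
    ents = pd.read_csv(
        entities_path, sep="\t", dtype={"start": int, "end": int}, keep_default_na=False
    )
    by_key: dict[tuple[str, str], list[EntityMention]] = {}
    for row in ents.itertuples(index=False):
        semtypes = tuple(str(row.semtypes).split("|"))
        if type_group_map:
            groups = tuple(type_group_map.get(t, t) for t in semtypes)
        else:
            groups = semtypes
        key = (str(row.doc_id), str(row.sentence_id))
        sent_text = None  # filled below via join
        by_key.setdefault(key, []).append(
            EntityMention(
                surface="",  # placeholder, replaced after join
                span=(int(row.start), int(row.end)),
                concept_id=str(row.cui),
                preferred_name=str(row.name),
                semantic_types=semtypes,
                semantic_groups=groups,
            )
        )
    out: list[SentenceRecord] = []
    for row in sents.itertuples(index=False):
        key = (str(row.doc_id), str(row.sentence_id))
        text = str(row.text)
        mentions = tuple(
            sorted(
                (
                    EntityMention(
                        surface=text[m.span[0] : m.span[1]],
                        span=m.span,
                        concept_id=m.concept_id,
                        preferred_name=m.preferred_name,
                        semantic_types=m.semantic_types,
                        semantic_groups=m.semantic_groups,
                    )
                    for m in by_key.get(key, [])
                ),
                key=lambda m: m.span,
            )
        )
        out.append(
            SentenceRecord(
                doc_id=key[0], sentence_id=key[1], text=text, entities=mentions
            )
        )
    return out
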