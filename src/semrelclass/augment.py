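"""EDA-style augmentation producing positive pairs for contrastive
pre-training.

Each training sample yields ``n_variants`` (default two) perturbed copies:
synonym replacement, random swap, random deletion and random insertion over
*context* tokens only.  The four marker tokens and every token inside the
marker-enclosed argument regions are immutable — perturbing the arguments
would corrupt the relation semantics the positive pair must preserve.  The
synonym lexicon is pluggable (flat TSV: term, pipe-separated synonyms); a
concept-derived lexicon may be supplied but is not required.
"""

from __future__ import annotations

import csv
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus import MarkedSequence

__all__ = [
    "AugmentationConfig",
    "ContrastiveBatch",
    "augment",
    "build_contrastive_batches",
    "load_synonym_lexicon",
    "save_synonym_lexicon",
]


@dataclass(frozen=True)
class AugmentationConfig:
    synonym_lexicon: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    p_synonym: float = 0.1
    p_swap: float = 0.1
    p_delete: float = 0.1
    p_insert: float = 0.1
    n_variants: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_synonym", "p_swap", "p_delete", "p_insert"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1]: {p}")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        object.__setattr__(
            self,
            "synonym_lexicon",
            {k: tuple(v) for k, v in dict(self.synonym_lexicon).items()},
        )


def load_synonym_lexicon(path: str | Path) -> dict[str, tuple[str, ...]]:
    out: dict[str, tuple[str, ...]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader, None)
        for row in reader:
            if len(row) >= 2 and row[0]:
                out[row[0]] = tuple(s for s in row[1].split("|") if s)
    return out


def save_synonym_lexicon(lexicon: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["term", "synonyms"])
        for term in sorted(lexicon):
            writer.writerow([term, "|".join(lexicon[term])])


def _segments(sample: MarkedSequence) -> list[tuple[str, bool]]:
    """Split the marked text into (piece, is_argument) segments in order."""
    spans = sorted([sample.subject_span, sample.object_span])
    # nested argument spans: treat the outer region as one immutable block
    if spans[0][1] >= spans[1][1]:
        spans = [spans[0]]
    elif spans[1][0] < spans[0][1]:
        spans = [(spans[0][0], spans[1][1])]
    text = sample.text
    out: list[tuple[str, bool]] = []
    cursor = 0
    for s, e in spans:
        if s > cursor:
            out.append((text[cursor:s], False))
        out.append((text[s:e], True))
        cursor = e
    if cursor < len(text):
        out.append((text[cursor:], False))
    return out


def _variant_rng(config: AugmentationConfig, origin: str, variant: int) -> np.random.Generator:
    h = zlib.crc32(origin.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([config.seed, h, variant]))


def augment(sample: MarkedSequence, config: AugmentationConfig) -> list[MarkedSequence]:
    """Produce ``n_variants`` perturbed copies of ``sample``.

    Marker tokens and argument-region tokens are never touched; only
    context tokens are replaced, swapped, deleted, or used as insertion
    anchors.  Deterministic under the config seed.  A sample with no
    perturbable context returns verbatim copies.
    """
    segments = _segments(sample)
    variants: list[MarkedSequence] = []
    for v in range(config.n_variants):
        rng = _variant_rng(config, sample.instance_id, v)
        # tokens: list of (token, immutable?)
        tokens: list[tuple[str, bool]] = []
        for piece, is_arg in segments:
            if is_arg:
                tokens.append((piece, True))
            else:
                tokens.extend((w, False) for w in piece.split())

        ctx_idx = [i for i, (_, imm) in enumerate(tokens) if not imm]

        # synonym replacement
        for i in ctx_idx:
            word = tokens[i][0]
            syns = config.synonym_lexicon.get(word)
            if syns and rng.random() < config.p_synonym:
                tokens[i] = (syns[int(rng.integers(len(syns)))], False)

        # random swap (context positions only)
        if len(ctx_idx) >= 2:
            for i in ctx_idx:
                if rng.random() < config.p_swap:
                    j = int(rng.choice(ctx_idx))
                    tokens[i], tokens[j] = (
                        (tokens[j][0], False),
                        (tokens[i][0], False),
                    )

        # random deletion
        keep: list[tuple[str, bool]] = []
        for tok, imm in tokens:
            if not imm and rng.random() < config.p_delete:
                continue
            keep.append((tok, imm))
        tokens = keep

        # random insertion: a synonym of a random context word, next to it
        ctx_now = [i for i, (_, imm) in enumerate(tokens) if not imm]
        inserts: list[tuple[int, str]] = []
        for i in ctx_now:
            if rng.random() < config.p_insert:
                syns = config.synonym_lexicon.get(tokens[i][0])
                if syns:
                    inserts.append((i + 1, syns[int(rng.integers(len(syns)))]))
        for pos, word in sorted(inserts, reverse=True):
            tokens.insert(pos, (word, False))

        text = " ".join(t for t, _ in tokens)
        m = sample.markers
        s0 = text.index(m.subj_open)
        s1 = text.index(m.subj_close) + len(m.subj_close)
        o0 = text.index(m.obj_open)
        o1 = text.index(m.obj_close) + len(m.obj_close)
        variants.append(
            MarkedSequence(
                text=text,
                subject_span=(s0, s1),
                object_span=(o0, o1),
                label=sample.label,
                instance_id=sample.instance_id,
                markers=m,
            )
        )
    return variants


@dataclass(frozen=True)
class ContrastiveBatch:
    """2N augmented sequences; the two variants of each source form the
    positive pair.  ``origin_ids[i]`` identifies the source of sequence i."""

    sequences: tuple[MarkedSequence, ...]
    origin_ids: tuple[str, ...]

    @property
    def n_sources(self) -> int:
        return len(self.sequences) // 2

    def partner_index(self) -> np.ndarray:
        """For each anchor, the index of its positive partner."""
        out = np.empty(len(self.sequences), dtype=np.int64)
        by_origin: dict[str, list[int]] = {}
        for i, oid in enumerate(self.origin_ids):
            by_origin.setdefault(oid, []).append(i)
        for pair in by_origin.values():
            if len(pair) != 2:
                raise ValueError("each origin must appear exactly twice in a batch")
            out[pair[0]], out[pair[1]] = pair[1], pair[0]
        return out


def build_contrastive_batches(
    samples: Sequence[MarkedSequence],
    batch_size: int = 16,
    config: AugmentationConfig | None = None,
) -> list[ContrastiveBatch]:
    """Chunk sources into batches of ``batch_size`` and augment each into a
    positive pair.  A final ragged chunk is kept if it has at least two
    sources (one source alone has no negatives and is dropped)."""
    if batch_size < 2:
        raise ValueError("batch_size must be >= 2 source samples")
    config = config or AugmentationConfig()
    if config.n_variants != 2:
        raise ValueError("contrastive batches require exactly two variants per source")
    batches: list[ContrastiveBatch] = []
    for start in range(0, len(samples), batch_size):
        chunk = samples[start : start + batch_size]
        if len(chunk) < 2:
            continue
        seqs: list[MarkedSequence] = []
        origins: list[str] = []
        for src in chunk:
            pair = augment(src, config)
            seqs.extend(pair)
            origins.extend([src.instance_id, src.instance_id])
        batches.append(ContrastiveBatch(tuple(seqs), tuple(origins)))
    return batches
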