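"""Relation-classification model: contrastive pre-training objective,
entity-marker encoding, mean-pooled entity representations, the three-branch
classification head, class-weighted cross-entropy, and the training loop.

The classifier consumes a sentence-summary vector plus mean-pooled subject
and object representations (marker tokens included), each passed through an
independent feed-forward branch (linear, dropout 0.1, tanh, layer norm); the
concatenation is mapped to 23 label scores.  Pre-training minimises a
temperature-scaled cosine-similarity contrastive loss over augmentation
positive pairs, through a projection head that is discarded afterwards.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .augment import AugmentationConfig, ContrastiveBatch, build_contrastive_batches
from .corpus import (
    DEFAULT_MARKERS,
    MarkedSequence,
    MarkerSet,
    insert_markers,
    substitute_representation,
)
from .encoder import (
    SequenceTooLongError,
    TinyTransformerBackend,
    WordTokenizer,
)
from .nn import Adam, Tensor, concat, log_softmax, softmax
from .schema import N_LABELS, RelationInstance, RelationLabel

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "DegenerateBatchError",
    "contrastive_loss",
    "pool_entity",
    "batch_class_weights",
    "weighted_cross_entropy",
    "ProjectionHead",
    "ClassifierHead",
    "RelationClassifier",
    "train_model",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    The defaults are the fine-tuning settings for a pretrained encoder
    (epochs 10, batch 16, max length 384, Adam lr 5e-5 / eps 1e-8,
    contrastive temperature 0.1).  A randomly initialised small backbone
    trains from scratch and conventionally needs a larger rate (~1e-3).
    """

    epochs: int = 10
    batch_size: int = 16
    max_length: int = 384
    learning_rate: float = 5e-5
    adam_epsilon: float = 1e-8
    temperature: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        for name in ("batch_size", "max_length", "learning_rate", "adam_epsilon", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class DegenerateBatchError(ValueError):
    """A contrastive batch with fewer than two sources has no negatives."""


# --- losses and pooling -----------------------------------------------------


def contrastive_loss(
    embeddings: Tensor,
    partner_index: np.ndarray,
    temperature: float = 0.1,
    strict: bool = True,
) -> Tensor:
    """Temperature-scaled cosine-similarity contrastive loss, averaged over
    all 2N anchors.

    For anchor z' with positive partner z'', the per-anchor term is
    -log( exp(sim(z',z'')/t) / sum_{k != anchor} exp(sim(z',z_k)/t) ),
    with cosine similarity and the denominator running over every vector in
    the batch except the anchor itself (identity, not value, comparison).
    With ``strict`` a batch of N < 2 sources raises; the N = 1 value is
    still defined (numerator equals denominator, loss exactly 0) and is
    computed when ``strict`` is false.
    """
    two_n = embeddings.shape[0]
    if two_n % 2 or two_n == 0:
        raise ValueError("embeddings must hold 2N vectors")
    if strict and two_n < 4:
        raise DegenerateBatchError("contrastive batch needs at least 2 sources")
    if temperature <= 0:
        raise ValueError("temperature must be positive")

    norms = (embeddings**2.0).sum(axis=1, keepdims=True) ** 0.5
    z = embeddings / norms
    sims = (z @ z.transpose()) * (1.0 / temperature)
    sims = sims + Tensor(np.where(np.eye(two_n, dtype=bool), -1e9, 0.0))
    logp = log_softmax(sims, axis=1)
    picked = logp[(np.arange(two_n), np.asarray(partner_index))]
    return -picked.mean()


def pool_entity(token_vectors: Tensor, span: tuple[int, int]) -> Tensor:
    """Arithmetic mean of the token vectors over a half-open token span
    (marker tokens included)."""
    s, e = span
    if not s < e:
        raise ValueError(f"empty entity token span {span}")
    return token_vectors[s:e].mean(axis=0)


def batch_class_weights(labels: Sequence[RelationLabel]) -> dict[RelationLabel, float]:
    """Balanced inverse-frequency weights w_c = B / (C * n_c).

    B is the batch size, C the number of classes present, n_c the count of
    class c; absent classes get weight 0.  Rarer classes receive strictly
    larger weights, counteracting class imbalance within the batch.
    """
    if not labels:
        raise ValueError("empty batch")
    counts: dict[RelationLabel, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    B, C = len(labels), len(counts)
    return {lab: B / (C * n) for lab, n in counts.items()}


def weighted_cross_entropy(
    logits: Tensor, labels: Sequence[RelationLabel],
    weights: Mapping[RelationLabel, float] | None = None,
) -> Tensor:
    """Class-weighted cross-entropy, normalised by the sum of the applied
    weights (so all-equal weights reduce to the unweighted mean)."""
    idx = np.array([lab.index for lab in labels])
    logp = log_softmax(logits, axis=1)
    picked = logp[(np.arange(len(labels)), idx)]
    if weights is None:
        return -picked.mean()
    w = np.array([weights.get(lab, 0.0) for lab in labels])
    return -(picked * Tensor(w)).sum() * (1.0 / w.sum())


# --- heads ------------------------------------------------------------------


def _dropout(x: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when rng is None (evaluation mode)."""
    if rng is None or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


class ProjectionHead:
    """Feed-forward projection used only during contrastive pre-training:
    linear, dropout 0.1, tanh.  Discarded before fine-tuning."""

    def __init__(self, in_dim: int, out_dim: int, seed: int = 0, dropout: float = 0.1):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 211]))
        self.w = Tensor(rng.normal(0, 1 / np.sqrt(in_dim), (in_dim, out_dim)), requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)
        self.dropout = dropout

    def parameters(self) -> list[Tensor]:
        return [self.w, self.b]

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        return _dropout(x @ self.w + self.b, self.dropout, rng).tanh()


class _Branch:
    def __init__(self, rng: np.random.Generator, dim: int, dropout: float):
        self.w = Tensor(rng.normal(0, 1 / np.sqrt(dim), (dim, dim)), requires_grad=True)
        self.b = Tensor(np.zeros(dim), requires_grad=True)
        self.ln_g = Tensor(np.ones(dim), requires_grad=True)
        self.ln_b = Tensor(np.zeros(dim), requires_grad=True)
        self.dropout = dropout

    def parameters(self) -> list[Tensor]:
        return [self.w, self.b, self.ln_g, self.ln_b]

    def __call__(self, x: Tensor, rng: np.random.Generator | None) -> Tensor:
        h = _dropout(x @ self.w + self.b, self.dropout, rng).tanh()
        mu = h.mean(axis=-1, keepdims=True)
        var = ((h - mu) ** 2.0).mean(axis=-1, keepdims=True)
        return (h - mu) * ((var + 1e-5) ** -0.5) * self.ln_g + self.ln_b


class ClassifierHead:
    """Three independent branches (sentence summary, subject, object), each
    linear + dropout 0.1 + tanh + layer norm, concatenated and mapped to the
    23 label scores."""

    def __init__(self, hidden_size: int, seed: int = 0, dropout: float = 0.1):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 223]))
        self.sent = _Branch(rng, hidden_size, dropout)
        self.subj = _Branch(rng, hidden_size, dropout)
        self.obj = _Branch(rng, hidden_size, dropout)
        self.w_out = Tensor(
            rng.normal(0, 1 / np.sqrt(3 * hidden_size), (3 * hidden_size, N_LABELS)),
            requires_grad=True,
        )
        self.b_out = Tensor(np.zeros(N_LABELS), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return (
            self.sent.parameters()
            + self.subj.parameters()
            + self.obj.parameters()
            + [self.w_out, self.b_out]
        )

    def logits(
        self,
        sentence_vec: Tensor,
        subject_vec: Tensor,
        object_vec: Tensor,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        h = concat(
            [self.sent(sentence_vec, rng), self.subj(subject_vec, rng), self.obj(object_vec, rng)],
            axis=-1,
        )
        return h @ self.w_out + self.b_out


def classify(
    sentence_vec: Tensor, subject_vec: Tensor, object_vec: Tensor, head: ClassifierHead
) -> np.ndarray:
    """Probability vector over the 23 labels (evaluation mode, no dropout)."""
    return softmax(head.logits(sentence_vec, subject_vec, object_vec), axis=-1).data


# --- sample encoding --------------------------------------------------------


def token_spans(sample: MarkedSequence, tokenizer: WordTokenizer) -> tuple[list[int], tuple[int, int], tuple[int, int]]:
    """Token ids (with [CLS]) and the half-open token spans of the two
    marker-enclosed regions, markers included.

    A marker split into several tokens is a construction error: each marker
    must occur exactly once as an atomic token.
    """
    ids = tokenizer.encode(sample.text)
    mids = tokenizer.marker_ids()
    m = sample.markers
    pos: dict[str, int] = {}
    for name in m.all():
        tid = mids[name]
        hits = [i for i, t in enumerate(ids) if t == tid]
        if len(hits) != 1:
            raise ValueError(
                f"marker {name!r} must occur exactly once as an atomic token "
                f"(found {len(hits)})"
            )
        pos[name] = hits[0]
    subj = (pos[m.subj_open], pos[m.subj_close] + 1)
    obj = (pos[m.obj_open], pos[m.obj_close] + 1)
    if subj[1] - subj[0] < 3 or obj[1] - obj[0] < 3:
        raise ValueError("argument region must hold open + >=1 token + close")
    return ids, subj, obj


def encode_sample(
    sample: MarkedSequence, backend: TinyTransformerBackend
) -> tuple[np.ndarray, np.ndarray, tuple[int, int], tuple[int, int]]:
    """Encode one marked sample: per-token vectors from the last hidden
    layer, the sentence-summary vector, and the subject/object token spans.

    Sequences longer than the backend's maximum length raise
    :class:`SequenceTooLongError`; callers exclude, count and report them.
    """
    ids, subj, obj = token_spans(sample, backend.tokenizer)
    tokens, cls_vec, _ = backend.encode_ids([ids])
    return tokens.data[0], cls_vec.data[0], subj, obj


# --- the trainable model ----------------------------------------------------


class RelationClassifier:
    """Encoder backbone + classifier head with fit / predict / persistence."""

    def __init__(
        self,
        backend: TinyTransformerBackend,
        seed: int = 0,
        markers: MarkerSet = DEFAULT_MARKERS,
    ):
        self.backend = backend
        self.markers = markers
        self.seed = seed
        self.head = ClassifierHead(backend.hidden_size, seed=seed)
        self.label_order = [lab.name for lab in RelationLabel.ordered()]
        self.skipped_too_long = 0

    # -- internals -----------------------------------------------------------
    def _forward(
        self, samples: Sequence[MarkedSequence], rng: np.random.Generator | None
    ) -> Tensor:
        prepared = [token_spans(s, self.backend.tokenizer) for s in samples]
        for ids, _, _ in prepared:
            if len(ids) > self.backend.max_length:
                raise SequenceTooLongError(str(len(ids)))
        tokens, cls_vec, _ = self.backend.encode_ids([p[0] for p in prepared])
        subj_vecs = []
        obj_vecs = []
        for i, (_, subj, obj) in enumerate(prepared):
            row = tokens[i]
            subj_vecs.append(pool_entity(row, subj).reshape(1, -1))
            obj_vecs.append(pool_entity(row, obj).reshape(1, -1))
        subj_mat = concat(subj_vecs, axis=0)
        obj_mat = concat(obj_vecs, axis=0)
        return self.head.logits(cls_vec, subj_mat, obj_mat, rng)

    def _filter_by_length(
        self, samples: Sequence[MarkedSequence]
    ) -> list[MarkedSequence]:
        kept = []
        for s in samples:
            n = len(self.backend.tokenizer.encode(s.text))
            if n > self.backend.max_length:
                self.skipped_too_long += 1
                logger.warning(
                    "skipping %s: %d tokens exceeds max_length=%d",
                    s.instance_id, n, self.backend.max_length,
                )
            else:
                kept.append(s)
        return kept

    # -- training ------------------------------------------------------------
    def pretrain(
        self,
        samples: Sequence[MarkedSequence],
        config: TrainConfig,
        aug_config: AugmentationConfig | None = None,
    ) -> list[float]:
        """Contrastive pre-training on augmentation positive pairs; the
        projection head is used here only and then discarded."""
        samples = self._filter_by_length(list(samples))
        aug_config = aug_config or AugmentationConfig(seed=config.seed)
        projection = ProjectionHead(self.backend.hidden_size, self.backend.hidden_size, seed=config.seed)
        opt = Adam(
            self.backend.parameters() + projection.parameters(),
            lr=config.learning_rate, eps=config.adam_epsilon,
        )
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 307]))
        history: list[float] = []
        order_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 311]))
        for _ in range(config.epochs):
            order = order_rng.permutation(len(samples))
            shuffled = [samples[i] for i in order]
            batches = build_contrastive_batches(shuffled, config.batch_size, aug_config)
            epoch_loss = 0.0
            for batch in batches:
                prepared = [token_spans(s, self.backend.tokenizer) for s in batch.sequences]
                _, cls_vec, _ = self.backend.encode_ids([p[0] for p in prepared])
                z = projection(cls_vec, rng)
                loss = contrastive_loss(z, batch.partner_index(), config.temperature)
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += loss.item() * batch.n_sources
            history.append(epoch_loss / max(len(samples), 1))
        return history

    def fit(
        self,
        samples: Sequence[MarkedSequence],
        config: TrainConfig,
        class_weighting: bool = True,
        batch_callback=None,
    ) -> list[float]:
        """Supervised fine-tuning with class-weighted cross-entropy.

        ``batch_callback``, if given, receives the instance ids of every
        batch in order — the supervised batch stream is a pure function of
        the seed, untouched by whether pre-training ran first."""
        samples = self._filter_by_length(list(samples))
        opt = Adam(
            self.backend.parameters() + self.head.parameters(),
            lr=config.learning_rate, eps=config.adam_epsilon,
        )
        drop_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 401]))
        order_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 409]))
        history: list[float] = []
        for _ in range(config.epochs):
            order = order_rng.permutation(len(samples))
            epoch_loss = 0.0
            for start in range(0, len(samples), config.batch_size):
                batch = [samples[i] for i in order[start : start + config.batch_size]]
                if batch_callback is not None:
                    batch_callback([s.instance_id for s in batch])
                labels = [s.label for s in batch]
                logits = self._forward(batch, drop_rng)
                weights = batch_class_weights(labels) if class_weighting else None
                loss = weighted_cross_entropy(logits, labels, weights)
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += loss.item() * len(batch)
            history.append(epoch_loss / max(len(samples), 1))
        return history

    # -- inference -----------------------------------------------------------
    def predict_proba(
        self, samples: Sequence[MarkedSequence], batch_size: int = 64
    ) -> np.ndarray:
        """(n, 23) probability matrix in the fixed label order; evaluation
        mode (no dropout), deterministic."""
        out = np.empty((len(samples), N_LABELS))
        for start in range(0, len(samples), batch_size):
            chunk = list(samples[start : start + batch_size])
            logits = self._forward(chunk, rng=None)
            out[start : start + len(chunk)] = softmax(logits, axis=-1).data
        return out

    # -- persistence ---------------------------------------------------------
    def save(self, ckpt_dir: str | Path, config: TrainConfig | None = None) -> None:
        ckpt = Path(ckpt_dir)
        ckpt.mkdir(parents=True, exist_ok=True)
        arrays = self.backend.state_arrays()
        for i, p in enumerate(self.head.parameters()):
            arrays[f"head{i}"] = p.data
        np.savez(ckpt / "parameters.npz", **arrays)
        meta = {
            "label_order": self.label_order,
            "markers": list(self.markers.all()),
            "seed": self.seed,
            "hidden_size": self.backend.hidden_size,
            "n_layers": self.backend.n_layers,
            "n_heads": self.backend.n_heads,
            "max_length": self.backend.max_length,
            "vocab": self.backend.tokenizer.vocab,
            "config": asdict(config) if config else None,
        }
        (ckpt / "meta.json").write_text(json.dumps(meta), encoding="utf-8")

    @classmethod
    def load(cls, ckpt_dir: str | Path) -> "RelationClassifier":
        ckpt = Path(ckpt_dir)
        meta = json.loads((ckpt / "meta.json").read_text(encoding="utf-8"))
        mk = MarkerSet(*meta["markers"])
        tok = WordTokenizer(markers=mk)
        tok.vocab = {k: int(v) for k, v in meta["vocab"].items()}
        backend = TinyTransformerBackend(
            tok,
            hidden_size=meta["hidden_size"],
            n_layers=meta["n_layers"],
            n_heads=meta["n_heads"],
            max_length=meta["max_length"],
            seed=meta["seed"],
        )
        obj = cls(backend, seed=meta["seed"], markers=mk)
        with np.load(ckpt / "parameters.npz") as arrays:
            backend.load_state_arrays({k: arrays[k] for k in arrays.files if k.startswith("p")})
            for i, p in enumerate(obj.head.parameters()):
                p.data[...] = arrays[f"head{i}"]
        return obj


# --- orchestration ----------------------------------------------------------


def prepare_samples(
    instances: Sequence[RelationInstance],
    representation: str = "mention",
    markers: MarkerSet = DEFAULT_MARKERS,
) -> list[MarkedSequence]:
    """Substitute the entity representation and insert markers."""
    return [
        insert_markers(substitute_representation(inst, representation), markers)
        for inst in instances
    ]


def train_model(
    instances: Sequence[RelationInstance],
    config: TrainConfig,
    backend: TinyTransformerBackend | None = None,
    pretrain: bool = False,
    representation: str = "mention",
    aug_config: AugmentationConfig | None = None,
    markers: MarkerSet = DEFAULT_MARKERS,
    hidden_size: int = 64,
    n_layers: int = 2,
) -> tuple[RelationClassifier, dict[str, list[float]]]:
    """Train a relation classifier on the train split of ``instances``.

    With ``pretrain`` the backbone first runs contrastive pre-training on
    augmented train samples (projection head discarded afterwards), then
    supervised fine-tuning.  Pre-training and fine-tuning draw from
    separate seeded random streams, so the supervised batches are identical
    with and without pre-training for a fixed seed.
    """
    splits = {inst.split for inst in instances}
    if "train" not in splits:
        raise ValueError("corpus has no train split")
    if "val" not in splits:
        raise ValueError("corpus has no val split")
    train_insts = [i for i in instances if i.split == "train"]
    samples = prepare_samples(train_insts, representation, markers)

    if backend is None:
        tokenizer = WordTokenizer(markers=markers)
        all_samples = prepare_samples(list(instances), representation, markers)
        tokenizer.fit(s.text for s in all_samples)
        backend = TinyTransformerBackend(
            tokenizer,
            hidden_size=hidden_size,
            n_layers=n_layers,
            max_length=config.max_length,
            seed=config.seed,
        )
    clf = RelationClassifier(backend, seed=config.seed, markers=markers)
    history: dict[str, list[float]] = {"pretrain": [], "train": []}
    if config.epochs == 0:
        return clf, history
    if pretrain:
        history["pretrain"] = clf.pretrain(samples, config, aug_config)
    history["train"] = clf.fit(samples, config)
    return clf, history
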