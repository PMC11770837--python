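"""Encoder backends.

The ``EncoderBackend`` contract mirrors a BERT-style encoder: a tokenizer in
which the four entity-marker tokens are atomic vocabulary items, a maximum
sequence length of 384, and an ``encode`` producing per-token vectors from
the last hidden layer plus a sentence-summary vector (the [CLS] position).

``TinyTransformerBackend`` is a small, randomly initialised, fully seeded
transformer with the same contract, so the whole pipeline runs end to end
without any pretrained-weight download.  A pretrained biomedical encoder can
be plugged in by implementing the same interface.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .corpus import DEFAULT_MARKERS, MarkerSet
from .nn import Tensor, softmax

__all__ = ["WordTokenizer", "SequenceTooLongError", "TinyTransformerBackend"]

MAX_LENGTH = 384

PAD, UNK, CLS = "[PAD]", "[UNK]", "[CLS]"


class SequenceTooLongError(ValueError):
    """Tokenized length exceeds the backend's maximum sequence length."""


class WordTokenizer:
    """Whitespace/punctuation tokenizer with atomic special tokens.

    The marker strings are matched before any generic token pattern, so a
    marker can never be split — the atomicity the entity-pooling step
    relies on.
    """

    def __init__(self, markers: MarkerSet = DEFAULT_MARKERS, lowercase: bool = False):
        self.markers = markers
        self.lowercase = lowercase
        specials = sorted(markers.all(), key=len, reverse=True)
        pattern = "|".join(re.escape(m) for m in specials) + r"|\w+|[^\w\s]"
        self._re = re.compile(pattern)
        self.vocab: dict[str, int] = {PAD: 0, UNK: 1, CLS: 2}
        for m in markers.all():
            self.vocab[m] = len(self.vocab)

    def tokenize(self, text: str) -> list[str]:
        toks = self._re.findall(text)
        if self.lowercase:
            marker_set = set(self.markers.all())
            toks = [t if t in marker_set else t.lower() for t in toks]
        return toks

    def fit(self, texts: Iterable[str]) -> "WordTokenizer":
        for text in texts:
            for tok in self.tokenize(text):
                if tok not in self.vocab:
                    self.vocab[tok] = len(self.vocab)
        return self

    def encode(self, text: str) -> list[int]:
        """Token ids with [CLS] prepended; unknown tokens map to [UNK]."""
        unk = self.vocab[UNK]
        ids = [self.vocab[CLS]]
        ids.extend(self.vocab.get(t, unk) for t in self.tokenize(text))
        return ids

    def marker_ids(self) -> dict[str, int]:
        return {m: self.vocab[m] for m in self.markers.all()}

    @property
    def vocab_size(self) -> int:
        return len(self.vocab)


def _init(rng: np.random.Generator, *shape: int, scale: float | None = None) -> Tensor:
    scale = scale if scale is not None else 1.0 / np.sqrt(shape[-1])
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


def _layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) ** 2.0).mean(axis=-1, keepdims=True)
    return (x - mu) * ((var + eps) ** -0.5) * gamma + beta


@dataclass
class _Layer:
    wq: Tensor
    wk: Tensor
    wv: Tensor
    wo: Tensor
    ln1_g: Tensor
    ln1_b: Tensor
    w1: Tensor
    b1: Tensor
    w2: Tensor
    b2: Tensor
    ln2_g: Tensor
    ln2_b: Tensor


class TinyTransformerBackend:
    """A small seeded transformer encoder satisfying the backend contract.

    Single-stack pre-softmax scaled dot-product attention with ``n_heads``
    heads, residual connections and layer normalisation, followed by a tanh
    feed-forward block per layer.  Default: 2 layers, 64 hidden units —
    deliberately tiny so CPU training on synthetic corpora stays fast.
    """

    def __init__(
        self,
        tokenizer: WordTokenizer,
        hidden_size: int = 64,
        n_layers: int = 2,
        n_heads: int = 4,
        ffn_size: int | None = None,
        max_length: int = MAX_LENGTH,
        seed: int = 0,
    ):
        if hidden_size % n_heads:
            raise ValueError("hidden_size must be divisible by n_heads")
        self.tokenizer = tokenizer
        self.hidden_size = hidden_size
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.ffn_size = ffn_size or 2 * hidden_size
        self.max_length = max_length
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
        d, f = hidden_size, self.ffn_size
        self.tok_emb = _init(rng, tokenizer.vocab_size, d, scale=0.02)
        self.pos_emb = _init(rng, max_length, d, scale=0.02)
        self.layers: list[_Layer] = []
        for _ in range(n_layers):
            self.layers.append(
                _Layer(
                    wq=_init(rng, d, d),
                    wk=_init(rng, d, d),
                    wv=_init(rng, d, d),
                    wo=_init(rng, d, d),
                    ln1_g=Tensor(np.ones(d), requires_grad=True),
                    ln1_b=Tensor(np.zeros(d), requires_grad=True),
                    w1=_init(rng, d, f),
                    b1=Tensor(np.zeros(f), requires_grad=True),
                    w2=_init(rng, f, d),
                    b2=Tensor(np.zeros(d), requires_grad=True),
                    ln2_g=Tensor(np.ones(d), requires_grad=True),
                    ln2_b=Tensor(np.zeros(d), requires_grad=True),
                )
            )

    # -- parameters ----------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        out = [self.tok_emb, self.pos_emb]
        for layer in self.layers:
            out.extend(getattr(layer, f.name) for f in layer.__dataclass_fields__.values())
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data[...] = arrays[f"p{i}"]

    # -- forward -------------------------------------------------------------
    def encode_ids(
        self, id_batch: Sequence[Sequence[int]]
    ) -> tuple[Tensor, Tensor, np.ndarray]:
        """Encode a batch of token-id sequences.

        Returns (per-token hidden states (B, T, d) from the last layer,
        sentence-summary vectors (B, d) = the [CLS] position, and the
        boolean validity mask (B, T)).  Sequences longer than
        ``max_length`` raise :class:`SequenceTooLongError`.
        """
        B = len(id_batch)
        lengths = [len(ids) for ids in id_batch]
        for n in lengths:
            if n > self.max_length:
                raise SequenceTooLongError(
                    f"sequence of {n} tokens exceeds max_length={self.max_length}"
                )
        T = max(lengths)
        ids = np.zeros((B, T), dtype=np.int64)
        mask = np.zeros((B, T), dtype=bool)
        for i, seq in enumerate(id_batch):
            ids[i, : len(seq)] = seq
            mask[i, : len(seq)] = True

        h = self.tok_emb.take_rows(ids) + self.pos_emb.take_rows(
            np.broadcast_to(np.arange(T), (B, T))
        )
        # additive mask: padded keys get a large negative score
        attn_bias = np.where(mask[:, None, None, :], 0.0, -1e9)
        d_head = self.hidden_size // self.n_heads
        scale = 1.0 / np.sqrt(d_head)

        for layer in self.layers:
            q = h @ layer.wq
            k = h @ layer.wk
            v = h @ layer.wv

            def split_heads(x: Tensor) -> Tensor:
                return x.reshape(B, T, self.n_heads, d_head).transpose(0, 2, 1, 3)

            qh, kh, vh = split_heads(q), split_heads(k), split_heads(v)
            scores = (qh @ kh.transpose(0, 1, 3, 2)) * scale + Tensor(attn_bias)
            attn = softmax(scores, axis=-1)
            ctx = (attn @ vh).transpose(0, 2, 1, 3).reshape(B, T, self.hidden_size)
            h = _layer_norm(h + ctx @ layer.wo, layer.ln1_g, layer.ln1_b)
            ff = ((h @ layer.w1 + layer.b1).tanh()) @ layer.w2 + layer.b2
            h = _layer_norm(h + ff, layer.ln2_g, layer.ln2_b)

        cls_vec = h[:, 0, :]
        return h, cls_vec, mask
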