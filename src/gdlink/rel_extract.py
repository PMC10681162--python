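"""Relation extraction over gene-disease mention pairs.

A candidate pair's feature vector concatenates four pieces: the two span
representations from the NER side (max-pool + width embedding each), a
max-pooled vector over the tokens strictly between the two spans, and an
attention context — a weighted sum ``sum_i w_i x_i`` over the document's
token encodings with softmaxed scaled-dot-product weights, the query being
a projection of the candidate pair. A shallow 2-class softmax head turns
the features into a link probability; a pair is predicted linked iff
``p_link > 0.5`` (strictly). The relation loss is binary cross-entropy and
the joint training loss is its exact sum with the NER loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from gdlink import nn
from gdlink.corpus_io import EntityMention
from gdlink.encoding import EncodedDocument


@dataclass
class RelationCandidate:
    """An ordered (gene, disease) mention pair with token intervals."""

    gene: EntityMention
    disease: EntityMention
    gene_tokens: tuple[int, int]
    disease_tokens: tuple[int, int]
    p_link: float | None = None


@dataclass
class AttentionContext:
    """Normalized attention weights and the resulting weighted sum."""

    weights: np.ndarray  # (n,), non-negative, sums to 1
    context: nn.Tensor   # (1, d_value)


@dataclass
class LossComponents:
    ner: float
    re: float

    @property
    def total(self) -> float:
        return self.ner + self.re


def form_candidates(
    mentions: list[EntityMention],
    token_intervals: dict[str, tuple[int, int]],
    endpoints: tuple[str, str] = ("Gene", "Disease"),
) -> list[RelationCandidate]:
    """All (gene, disease) cross pairs of a document, gene first.

    Mentions duplicating an already-seen (span, type) collapse to one, so
    the candidate list has set semantics over span coordinates.
    """
    def unique(etype: str) -> list[EntityMention]:
        seen: set[tuple[int, int]] = set()
        out = []
        for m in mentions:
            if m.etype == etype and m.span not in seen:
                seen.add(m.span)
                out.append(m)
        return out

    return [
        RelationCandidate(
            gene=g, disease=d,
            gene_tokens=token_intervals[g.id],
            disease_tokens=token_intervals[d.id],
        )
        for g in unique(endpoints[0])
        for d in unique(endpoints[1])
    ]


def between_context(cand: RelationCandidate, enc: EncodedDocument) -> nn.Tensor:
    """Element-wise max over tokens strictly between the two spans.

    Adjacent spans (no strictly-between tokens) and overlapping spans both
    yield the zero vector — the identity element of an empty max pool.
    """
    (gs, ge), (ds, de) = cand.gene_tokens, cand.disease_tokens
    if gs <= ds:
        lo, hi = ge, ds
    else:
        lo, hi = de, gs
    if hi <= lo:  # adjacent or overlapping
        return nn.Tensor(np.zeros((1, enc.hidden)))
    return enc.embeddings[lo:hi].amax(axis=0).reshape(1, -1)


def attend(query: nn.Tensor, keys: nn.Tensor, values: nn.Tensor) -> AttentionContext:
    """Scaled-dot-product attention: softmax(q.K^T/sqrt(d)) weighted sum of values."""
    n = keys.shape[0]
    if n == 0:
        raise ValueError("cannot attend over zero tokens")
    scores = query @ keys.transpose(1, 0) * (1.0 / math.sqrt(keys.shape[1]))
    w = nn.softmax(scores, axis=-1)  # (1, n)
    return AttentionContext(weights=w.data.ravel().copy(), context=w @ values)


class RelationHead(nn.Module):
    """Query projection, optional recurrent key/value encoder, link scorer.

    ``seq2seq`` selects how attention keys/values are produced from the
    encoder output: "identity" passes the token encodings straight through;
    "birnn" runs one bidirectional recurrent layer (output width preserved).
    """

    def __init__(
        self,
        rng: np.random.Generator,
        hidden: int,
        span_dim: int,
        seq2seq: str = "identity",
        clf_hidden: int = 64,
    ) -> None:
        if seq2seq not in ("identity", "birnn"):
            raise ValueError(f"unknown seq2seq mode {seq2seq!r}")
        self.seq2seq = seq2seq
        self.hidden = hidden
        if seq2seq == "birnn":
            if hidden % 2:
                raise ValueError("birnn mode needs an even hidden width")
            self.rnn = nn.BiRecurrent(rng, hidden, hidden // 2)
        self.query_proj = nn.Linear(rng, 2 * hidden, hidden)
        feat = 2 * span_dim + 2 * hidden  # e_g ++ e_d ++ between ++ attention
        self.l1 = nn.Linear(rng, feat, clf_hidden)
        self.l2 = nn.Linear(rng, clf_hidden, 2)

    def keys_values(self, enc: EncodedDocument) -> nn.Tensor:
        if self.seq2seq == "birnn":
            return self.rnn(enc.embeddings)
        return enc.embeddings

    def features(
        self,
        cand: RelationCandidate,
        enc: EncodedDocument,
        span_reprs: dict[tuple[int, int], nn.Tensor],
        kv: nn.Tensor,
    ) -> nn.Tensor:
        e_g = span_reprs[cand.gene_tokens]
        e_d = span_reprs[cand.disease_tokens]
        pooled_g = enc.embeddings[cand.gene_tokens[0] : cand.gene_tokens[1]].amax(0).reshape(1, -1)
        pooled_d = enc.embeddings[cand.disease_tokens[0] : cand.disease_tokens[1]].amax(0).reshape(1, -1)
        query = self.query_proj(nn.concat([pooled_g, pooled_d], axis=-1))
        attn = attend(query, kv, kv).context
        return nn.concat([e_g, e_d, between_context(cand, enc), attn], axis=-1)

    def logits(self, feats: nn.Tensor) -> nn.Tensor:
        return self.l2(self.l1(feats).relu())


def score_link(logits: nn.Tensor) -> np.ndarray:
    """Positive-class probabilities from 2-class logits."""
    return nn.softmax(logits, axis=-1).data[:, 1].copy()


def predicted_link(p_link: float, threshold: float = 0.5) -> bool:
    """Linked iff the probability strictly exceeds the threshold."""
    return p_link > threshold


def re_loss(logits: nn.Tensor, labels: np.ndarray, reduction: str = "sum") -> nn.Tensor:
    """Binary cross-entropy over candidate link labels (2-class softmax form)."""
    return nn.cross_entropy(logits, labels, reduction=reduction)


def joint_loss(ner: nn.Tensor, re_bce: nn.Tensor) -> nn.Tensor:
    """The collaborative training loss: exact sum of NER and RE components."""
    for name, part in (("ner", ner), ("re", re_bce)):
        if not np.all(np.isfinite(part.data)):
            raise FloatingPointError(f"non-finite {name} loss component: {part.data}")
    return ner + re_bce
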