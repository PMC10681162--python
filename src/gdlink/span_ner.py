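"""Span-based named-entity recognition.

Every token interval up to a width cap is a candidate entity. A candidate's
representation is the element-wise max over its token embeddings
concatenated with a learned width embedding; a shallow classifier maps the
representation to 13 classes (the 12 entity types plus non-entity). The
training loss is the summed multiclass cross-entropy
``-sum_o sum_t y_{o,t} log p_{o,t}`` over gold spans plus sampled
non-entity spans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gdlink import nn
from gdlink.corpus_io import ENTITY_TYPES
from gdlink.encoding import EncodedDocument

#: Class order: the 12 entity types then the non-entity class.
CLASSES = list(ENTITY_TYPES) + ["<none>"]
NONE_IDX = len(ENTITY_TYPES)
TYPE_TO_IDX = {t: i for i, t in enumerate(ENTITY_TYPES)}


@dataclass(frozen=True)
class SpanCandidate:
    """Half-open token interval [i, j); width = j - i."""

    i: int
    j: int

    @property
    def width(self) -> int:
        return self.j - self.i


def enumerate_spans(n: int, max_width: int = 10) -> list[SpanCandidate]:
    """All token intervals of width 1..min(max_width, n), width-major order."""
    if n < 0 or max_width < 1:
        raise ValueError("need n >= 0 and max_width >= 1")
    return [
        SpanCandidate(i, i + w)
        for w in range(1, min(max_width, n) + 1)
        for i in range(n - w + 1)
    ]


class NerHead(nn.Module):
    """Width-embedding table plus a shallow span classifier.

    Widths beyond the table clamp to its last row. The classifier is a
    single hidden layer with ReLU followed by a linear map to 13 logits.
    """

    def __init__(
        self,
        rng: np.random.Generator,
        hidden: int,
        width_dim: int = 25,
        max_width: int = 10,
        clf_hidden: int = 64,
    ) -> None:
        self.hidden = hidden
        self.max_width = max_width
        self.width_table = nn.Embedding(rng, max_width, width_dim)
        self.l1 = nn.Linear(rng, hidden + width_dim, clf_hidden)
        self.l2 = nn.Linear(rng, clf_hidden, len(CLASSES))

    def width_embedding(self, widths: np.ndarray) -> nn.Tensor:
        clamped = np.minimum(np.asarray(widths, dtype=np.intp), self.max_width) - 1
        return self.width_table(clamped)

    def logits(self, reprs: nn.Tensor) -> nn.Tensor:
        return self.l2(self.l1(reprs).relu())


def pool_all_spans(enc: EncodedDocument, spans: list[SpanCandidate]) -> nn.Tensor:
    """Max-pooled vectors for spans listed in width-major enumeration order.

    Uses the running-max recurrence P_w[i] = max(P_{w-1}[i], E[i+w-1]) so the
    cost is O(max_width * n * H) rather than per-span.
    """
    if not spans:
        return nn.Tensor(np.zeros((0, enc.hidden)))
    E = enc.embeddings
    n = E.shape[0]
    max_w = max(s.width for s in spans)
    by_width: dict[int, nn.Tensor] = {}
    prev = E
    by_width[1] = prev
    for w in range(2, max_w + 1):
        prev = nn.maximum(prev[: n - w + 1], E[w - 1 :])
        by_width[w] = prev
    rows = [by_width[s.width][s.i : s.i + 1] for s in spans]
    return nn.concat(rows, axis=0)


def span_representation(
    span: SpanCandidate, enc: EncodedDocument, head: NerHead
) -> nn.Tensor:
    """Max-pool over the span's token vectors, concatenated with width embedding."""
    pooled = enc.embeddings[span.i : span.j].amax(axis=0).reshape(1, -1)
    wemb = head.width_embedding(np.array([span.width]))
    return nn.concat([pooled, wemb], axis=-1)


def classify_spans(
    spans: list[SpanCandidate], enc: EncodedDocument, head: NerHead
) -> nn.Tensor:
    """Logits (n_spans, 13) for a list of candidates."""
    pooled = pool_all_spans(enc, spans)
    wemb = head.width_embedding(np.array([s.width for s in spans], dtype=np.intp))
    return head.logits(nn.concat([pooled, wemb], axis=-1))


def predict_types(logits: nn.Tensor) -> tuple[np.ndarray, np.ndarray]:
    """(argmax class index, probability of that class) per span.

    Ties at the argmax break toward the lowest class index (numpy argmax).
    """
    p = nn.softmax(logits, axis=-1).data
    pred = p.argmax(axis=-1)
    return pred, p[np.arange(len(pred)), pred]


def ner_loss(
    logits: nn.Tensor, labels: np.ndarray, reduction: str = "sum"
) -> nn.Tensor:
    """Summed (default) cross-entropy over scored spans; >= 0, 0 for empty batch."""
    return nn.cross_entropy(logits, labels, reduction=reduction)


def sample_negative_spans(
    spans: list[SpanCandidate],
    gold: set[tuple[int, int]],
    n_neg: int,
    rng: np.random.Generator,
) -> list[int]:
    """Indices (into ``spans``) of up to ``n_neg`` sampled non-entity spans."""
    negatives = [k for k, s in enumerate(spans) if (s.i, s.j) not in gold]
    if len(negatives) <= n_neg:
        return negatives
    pick = rng.choice(len(negatives), size=n_neg, replace=False)
    return [negatives[int(k)] for k in sorted(pick)]


def resolve_conflicts(
    predictions: list[tuple[SpanCandidate, int, float]]
) -> list[tuple[SpanCandidate, int, float]]:
    """Keep one prediction per exact token span: the higher-probability type.

    Nested and overlapping spans of different extents are all retained; only
    identical-span, different-type conflicts are resolved.
    """
    best: dict[tuple[int, int], tuple[SpanCandidate, int, float]] = {}
    for span, cls, p in predictions:
        key = (span.i, span.j)
        if key not in best or p > best[key][2]:
            best[key] = (span, cls, p)
    return [best[k] for k in sorted(best)]
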