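"""The joint NER + relation-extraction estimator.

:class:`JointExtractor` is a scikit-learn-style estimator: hyperparameters
are constructor arguments, :meth:`fit` trains on a list of annotated
documents, fitted state lives in trailing-underscore attributes, and
:meth:`predict` annotates documents end-to-end. The two heads share one
contextual encoder and are trained collaboratively by adding the NER
cross-entropy and the relation binary cross-entropy into a single loss.

The ``only_re`` mode reproduces the benchmarking regime where ground-truth
entity mentions are supplied and only the relation head is learned;
``de_augment`` switches on direct-edge augmentation of the training
documents, which adds every trigger-mediated gene-disease pair to the
positive relation signal.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from gdlink import nn, rel_extract, span_ner
from gdlink.corpus_io import (
    LINKED_OF,
    AnnotatedDocument,
    EntityMention,
    RelationInstance,
    add_direct_edges,
)
from gdlink.encoding import (
    AlignmentError,
    BPETokenizer,
    EncoderSpec,
    TinyEncoder,
    align_span,
)
from gdlink.span_ner import NONE_IDX, TYPE_TO_IDX, CLASSES


class _DocState:
    """Precomputed per-document training state (tokenization, gold labels)."""

    def __init__(self, doc: AnnotatedDocument, tokenizer: BPETokenizer, max_width: int) -> None:
        self.doc = doc
        self.tok = tokenizer.tokenize(doc.text, doc_id=doc.doc_id)
        self.intervals: dict[str, tuple[int, int]] = {}
        for m in doc.mentions:
            try:
                self.intervals[m.id] = align_span(m.span, self.tok)
            except AlignmentError:
                continue
        # Gold span labels (token-interval -> class), skipping over-wide spans.
        self.gold_spans: dict[tuple[int, int], int] = {}
        for m in doc.mentions:
            iv = self.intervals.get(m.id)
            if iv and iv[1] - iv[0] <= max_width and iv not in self.gold_spans:
                self.gold_spans[iv] = TYPE_TO_IDX[m.etype]
        # Positive gene-disease pairs keyed by token-interval pairs.
        by_id = {m.id: m for m in doc.mentions}
        self.positive_pairs: set[tuple[tuple[int, int], tuple[int, int]]] = set()
        for r in doc.relations:
            a, b = by_id.get(r.e0), by_id.get(r.e1)
            if a is None or b is None:
                continue
            pair = None
            if a.etype == "Gene" and b.etype == "Disease":
                pair = (a.id, b.id)
            elif a.etype == "Disease" and b.etype == "Gene":
                pair = (b.id, a.id)
            if pair and pair[0] in self.intervals and pair[1] in self.intervals:
                self.positive_pairs.add((self.intervals[pair[0]], self.intervals[pair[1]]))


class JointExtractor(BaseEstimator):
    """Joint span-based NER and gene-disease link prediction.

    Parameters
    ----------
    hidden, layers, heads : tiny-encoder shape.
    vocab_size : BPE vocabulary cap (trained on the fit corpus).
    max_width : span-width cap in subwords for NER candidates.
    width_dim : width-embedding dimension.
    neg_spans : sampled non-entity spans per document per epoch.
    neg_pairs : sampled unlinked gene-disease pairs per document per epoch.
    epochs, batch_size, lr, warmup : AdamW schedule (linear warmup then decay).
    loss_reduction : "sum" (the printed formula) or "mean".
    seq2seq : "identity" or "birnn" keys/values for the attention context.
    only_re : train and predict with gold entities; NER head not trained.
    de_augment : apply direct-edge augmentation to the training documents.
    seed : controls initialization and negative sampling.
    """

    def __init__(
        self,
        hidden: int = 64,
        layers: int = 2,
        heads: int = 2,
        vocab_size: int = 400,
        max_width: int = 10,
        width_dim: int = 25,
        neg_spans: int = 100,
        neg_pairs: int = 50,
        epochs: int = 20,
        batch_size: int = 4,
        lr: float = 6e-5,
        warmup: float = 0.1,
        loss_reduction: str = "sum",
        seq2seq: str = "identity",
        only_re: bool = False,
        de_augment: bool = False,
        seed: int = 0,
    ) -> None:
        self.hidden = hidden
        self.layers = layers
        self.heads = heads
        self.vocab_size = vocab_size
        self.max_width = max_width
        self.width_dim = width_dim
        self.neg_spans = neg_spans
        self.neg_pairs = neg_pairs
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.warmup = warmup
        self.loss_reduction = loss_reduction
        self.seq2seq = seq2seq
        self.only_re = only_re
        self.de_augment = de_augment
        self.seed = seed

    # ------------------------------------------------------------------ fit
    def fit(self, corpus: list[AnnotatedDocument], y=None) -> "JointExtractor":
        if not corpus:
            raise ValueError("cannot fit on an empty corpus")
        docs = [add_direct_edges(d) for d in corpus] if self.de_augment else list(corpus)

        self.tokenizer_ = BPETokenizer.train([d.text for d in docs], vocab_size=self.vocab_size)
        spec = EncoderSpec(
            kind="tiny-trainable", hidden=self.hidden, layers=self.layers,
            heads=self.heads, vocab_size=self.tokenizer_.vocab_size,
        )
        self.encoder_ = TinyEncoder(spec, seed=self.seed)
        init_rng = np.random.default_rng(np.random.SeedSequence([self.seed, 202]))
        self.ner_head_ = span_ner.NerHead(
            init_rng, self.hidden, width_dim=self.width_dim, max_width=self.max_width
        )
        self.rel_head_ = rel_extract.RelationHead(
            init_rng, self.hidden, span_dim=self.hidden + self.width_dim, seq2seq=self.seq2seq
        )
        params = self.encoder_.parameters() + self.rel_head_.parameters()
        params += self.ner_head_.parameters()
        opt = nn.AdamW(params, lr=self.lr)

        states = [_DocState(d, self.tokenizer_, self.max_width) for d in docs]
        states = [s for s in states if s.tok.n > 0]
        sample_rng = np.random.default_rng(np.random.SeedSequence([self.seed, 303]))

        n_batches = (len(states) + self.batch_size - 1) // self.batch_size
        total_steps = self.epochs * n_batches
        self.loss_trace_ = []
        step = 0
        for _epoch in range(self.epochs):
            for b in range(n_batches):
                batch = states[b * self.batch_size : (b + 1) * self.batch_size]
                losses = [self._doc_loss(s, sample_rng) for s in batch]
                losses = [l for l in losses if l is not None]
                if not losses:
                    step += 1
                    continue
                total = losses[0]
                for l in losses[1:]:
                    total = total + l
                for p in params:
                    p.grad = None
                total.backward()
                step += 1
                opt.step(lr=nn.linear_warmup_decay(step, total_steps, self.lr, self.warmup))
                self.loss_trace_.append(float(total.item()))
        return self

    def _doc_loss(self, state: _DocState, rng: np.random.Generator) -> nn.Tensor | None:
        enc = self.encoder_.encode(state.tok)
        parts: list[nn.Tensor] = []

        spans = span_ner.enumerate_spans(state.tok.n, self.max_width)
        span_index = {(s.i, s.j): k for k, s in enumerate(spans)}

        if not self.only_re:
            gold_keys = set(state.gold_spans)
            neg_idx = span_ner.sample_negative_spans(spans, gold_keys, self.neg_spans, rng)
            scored = [span_index[k] for k in sorted(gold_keys)] + neg_idx
            labels = np.array(
                [state.gold_spans[(spans[k].i, spans[k].j)] if (spans[k].i, spans[k].j) in state.gold_spans
                 else NONE_IDX for k in scored],
                dtype=np.intp,
            )
            sub = [spans[k] for k in scored]
            logits = span_ner.classify_spans(sub, enc, self.ner_head_)
            parts.append(span_ner.ner_loss(logits, labels, reduction=self.loss_reduction))

        re_part = self._re_loss(state, enc, rng)
        if re_part is not None:
            parts.append(re_part)
        if not parts:
            return None
        if len(parts) == 1:
            return parts[0]
        return rel_extract.joint_loss(parts[0], parts[1])

    def _re_loss(self, state: _DocState, enc, rng: np.random.Generator) -> nn.Tensor | None:
        cands = rel_extract.form_candidates(state.doc.mentions, state.intervals)
        cands = [c for c in cands if c.gene.id in state.intervals and c.disease.id in state.intervals]
        if not cands:
            return None
        pos = [c for c in cands if (c.gene_tokens, c.disease_tokens) in state.positive_pairs]
        neg = [c for c in cands if (c.gene_tokens, c.disease_tokens) not in state.positive_pairs]
        if len(neg) > self.neg_pairs:
            pick = rng.choice(len(neg), size=self.neg_pairs, replace=False)
            neg = [neg[int(k)] for k in sorted(pick)]
        chosen = pos + neg
        labels = np.array([1] * len(pos) + [0] * len(neg), dtype=np.intp)
        feats = self._pair_features(chosen, enc)
        logits = self.rel_head_.logits(feats)
        return rel_extract.re_loss(logits, labels, reduction=self.loss_reduction)

    def _pair_features(self, cands, enc) -> nn.Tensor:
        kv = self.rel_head_.keys_values(enc)
        reprs: dict[tuple[int, int], nn.Tensor] = {}
        for c in cands:
            for iv in (c.gene_tokens, c.disease_tokens):
                if iv not in reprs:
                    reprs[iv] = span_ner.span_representation(
                        span_ner.SpanCandidate(*iv), enc, self.ner_head_
                    )
        rows = [self.rel_head_.features(c, enc, reprs, kv) for c in cands]
        return nn.concat(rows, axis=0)

    # -------------------------------------------------------------- predict
    def predict(
        self, docs: list[AnnotatedDocument], gold_entities: bool | None = None
    ) -> list[AnnotatedDocument]:
        """Annotate documents with predicted mentions and LinkedOf relations.

        ``gold_entities`` defaults to ``only_re``: when true, the input
        documents' mentions are kept and only links are predicted.
        """
        if gold_entities is None:
            gold_entities = self.only_re
        return [self._predict_doc(d, gold_entities) for d in docs]

    def _predict_doc(self, doc: AnnotatedDocument, gold_entities: bool) -> AnnotatedDocument:
        tok = self.tokenizer_.tokenize(doc.text, doc_id=doc.doc_id)
        if tok.n == 0:
            return AnnotatedDocument(doc_id=doc.doc_id, text=doc.text)
        enc = self.encoder_.encode(tok)

        if gold_entities:
            mentions = list(doc.mentions)
            intervals = {}
            for m in mentions:
                try:
                    intervals[m.id] = align_span(m.span, tok)
                except AlignmentError:
                    continue
        else:
            mentions, intervals = self._predict_mentions(doc, tok, enc)

        cands = rel_extract.form_candidates(
            [m for m in mentions if m.id in intervals], intervals
        )
        relations = []
        if cands:
            feats = self._pair_features(cands, enc)
            probs = rel_extract.score_link(self.rel_head_.logits(feats))
            for c, p in zip(cands, probs):
                c.p_link = float(p)
                if rel_extract.predicted_link(float(p)):
                    relations.append(
                        RelationInstance(e0=c.gene.id, e1=c.disease.id, rtype=LINKED_OF, direct=True)
                    )
        return AnnotatedDocument(
            doc_id=doc.doc_id, text=doc.text, mentions=mentions, relations=relations
        )

    def _predict_mentions(self, doc, tok, enc):
        spans = span_ner.enumerate_spans(tok.n, self.max_width)
        logits = span_ner.classify_spans(spans, enc, self.ner_head_)
        pred, prob = span_ner.predict_types(logits)
        keep = [
            (spans[k], int(pred[k]), float(prob[k]))
            for k in range(len(spans))
            if pred[k] != NONE_IDX
        ]
        keep = span_ner.resolve_conflicts(keep)
        mentions, intervals = [], {}
        for k, (span, cls, _p) in enumerate(keep):
            start = tok.offsets[span.i][0]
            end = tok.offsets[span.j - 1][1]
            mid = f"P{k}"
            mentions.append(
                EntityMention(
                    id=mid, doc_id=doc.doc_id, start=start, end=end,
                    etype=CLASSES[cls], surface=doc.text[start:end],
                )
            )
            intervals[mid] = (span.i, span.j)
        return mentions, intervals

    def predict_candidates(self, doc: AnnotatedDocument, gold_entities: bool | None = None):
        """Scored gene-disease candidates (with ``p_link``) for one document."""
        if gold_entities is None:
            gold_entities = self.only_re
        tok = self.tokenizer_.tokenize(doc.text, doc_id=doc.doc_id)
        if tok.n == 0:
            return []
        enc = self.encoder_.encode(tok)
        if gold_entities:
            intervals = {}
            for m in doc.mentions:
                try:
                    intervals[m.id] = align_span(m.span, tok)
                except AlignmentError:
                    continue
            mentions = [m for m in doc.mentions if m.id in intervals]
        else:
            mentions, intervals = self._predict_mentions(doc, tok, enc)
        cands = rel_extract.form_candidates(mentions, intervals)
        if cands:
            feats = self._pair_features(cands, enc)
            probs = rel_extract.score_link(self.rel_head_.logits(feats))
            for c, p in zip(cands, probs):
                c.p_link = float(p)
        return cands
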