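"""Training harness (5-fold CV) and graph-based evaluation.

Evaluation follows the knowledge-graph protocol: a gold graph is built from
the annotations, a prediction graph from the model output, and the two are
compared with a confusion matrix. Entity true positives are nodes matching
exactly on (document, span, type); relation true positives are undirected
edges whose both endpoints match gold nodes and which exist in gold.

For relation-level scoring of gene-disease link prediction, the gold edge
set can be taken either ``raw`` (only annotated direct gene-disease edges)
or as the ``closure`` (every gene-disease pair connected through a
trigger-interior path — the direct-edge closure). The closure is the
default so that models trained with and without direct-edge augmentation
are scored against the same target set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from pydantic import BaseModel

from gdlink.corpus_io import (
    LINKED_OF,
    AnnotatedDocument,
    add_direct_edges,
)
from gdlink.model import JointExtractor


class TrainConfig(BaseModel):
    """Hyperparameters of one training run (the CV harness shares it per arm)."""

    lr: float = 6e-5
    warmup: float = 0.1
    epochs: int = 20
    batch_size: int = 4
    folds: int = 5
    seed: int = 0
    de_augment: bool = False
    only_re: bool = False
    hidden: int = 64
    layers: int = 2
    heads: int = 2
    vocab_size: int = 400
    seq2seq: str = "identity"
    eval_target: str = "closure"  # "raw" | "closure"


def _metrics(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if (tp + fp) else 0.0  # zero-prediction convention
    r = tp / (tp + fn) if (tp + fn) else 0.0
    f = 2 * p * r / (p + r) if (p + r) else 0.0
    return p, r, f


@dataclass
class EvalReport:
    """Entity- and relation-level confusion counts with derived P/R/F1."""

    entity_tp: int = 0
    entity_fp: int = 0
    entity_fn: int = 0
    relation_tp: int = 0
    relation_fp: int = 0
    relation_fn: int = 0

    @property
    def entity_precision(self) -> float:
        return _metrics(self.entity_tp, self.entity_fp, self.entity_fn)[0]

    @property
    def entity_recall(self) -> float:
        return _metrics(self.entity_tp, self.entity_fp, self.entity_fn)[1]

    @property
    def entity_f1(self) -> float:
        return _metrics(self.entity_tp, self.entity_fp, self.entity_fn)[2]

    @property
    def relation_precision(self) -> float:
        return _metrics(self.relation_tp, self.relation_fp, self.relation_fn)[0]

    @property
    def relation_recall(self) -> float:
        return _metrics(self.relation_tp, self.relation_fp, self.relation_fn)[1]

    @property
    def relation_f1(self) -> float:
        return _metrics(self.relation_tp, self.relation_fp, self.relation_fn)[2]

    def as_dict(self) -> dict:
        return {
            "entity": {
                "tp": self.entity_tp, "fp": self.entity_fp, "fn": self.entity_fn,
                "precision": self.entity_precision, "recall": self.entity_recall,
                "f1": self.entity_f1,
            },
            "relation": {
                "tp": self.relation_tp, "fp": self.relation_fp, "fn": self.relation_fn,
                "precision": self.relation_precision, "recall": self.relation_recall,
                "f1": self.relation_f1,
            },
        }


@dataclass
class FoldSummary:
    """Per-fold reports plus mean +/- sd of the headline metrics."""

    reports: list[EvalReport] = field(default_factory=list)

    def mean_sd(self, metric: str) -> tuple[float, float]:
        vals = np.array([getattr(r, metric) for r in self.reports], dtype=float)
        return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0


def kfold_split(
    corpus: list[AnnotatedDocument], k: int = 5, seed: int = 0
) -> list[list[AnnotatedDocument]]:
    """Disjoint document-level folds; sizes differ by at most one.

    The first ``len(corpus) % k`` folds get the extra document. Deterministic
    under ``seed``.
    """
    if len(corpus) < k:
        raise ValueError(f"need at least {k} documents for {k} folds, got {len(corpus)}")
    order = np.random.default_rng(seed).permutation(len(corpus))
    base, rem = divmod(len(corpus), k)
    folds, pos = [], 0
    for f in range(k):
        size = base + (1 if f < rem else 0)
        folds.append([corpus[i] for i in order[pos : pos + size]])
        pos += size
    return folds


# ---------------------------------------------------------------------------
# Graph construction and comparison

def build_graph(
    docs: list[AnnotatedDocument],
    relation_scope: str = "all",
    eval_target: str = "raw",
) -> nx.Graph:
    """Knowledge graph over typed mentions; nodes keyed by (doc, span, type).

    ``relation_scope="all"`` keeps every annotated edge;
    ``relation_scope="gene-disease"`` keeps only gene-disease edges, where
    ``eval_target`` chooses the raw annotated edge set or the direct-edge
    closure (every trigger-mediated pair made explicit).
    """
    g = nx.Graph()
    for doc in docs:
        use = doc
        if relation_scope == "gene-disease" and eval_target == "closure":
            use = add_direct_edges(doc)
        by_id = {m.id: m for m in use.mentions}
        for m in use.mentions:
            g.add_node((use.doc_id, m.start, m.end, m.etype), surface=m.surface)
        for r in use.relations:
            a, b = by_id[r.e0], by_id[r.e1]
            if relation_scope == "gene-disease" and {a.etype, b.etype} != {"Gene", "Disease"}:
                continue
            u = (use.doc_id, a.start, a.end, a.etype)
            v = (use.doc_id, b.start, b.end, b.etype)
            g.add_edge(u, v, rtype=r.rtype)
    return g


def compare_graphs(gold: nx.Graph, pred: nx.Graph) -> EvalReport:
    """Confusion-matrix comparison of a prediction graph against gold.

    Entity TP: exact node match on (doc, span, type). Relation TP: an
    undirected predicted edge whose both endpoints are gold nodes and which
    exists in gold. Precision with zero predictions is reported as 0.
    """
    gold_nodes, pred_nodes = set(gold.nodes), set(pred.nodes)
    e_tp = len(gold_nodes & pred_nodes)
    gold_edges = {frozenset(e) for e in gold.edges}
    r_tp = r_fp = 0
    for e in pred.edges:
        u, v = e
        if u in gold_nodes and v in gold_nodes and frozenset(e) in gold_edges:
            r_tp += 1
        else:
            r_fp += 1
    return EvalReport(
        entity_tp=e_tp,
        entity_fp=len(pred_nodes - gold_nodes),
        entity_fn=len(gold_nodes - pred_nodes),
        relation_tp=r_tp,
        relation_fp=r_fp,
        relation_fn=len(gold_edges) - len({frozenset(e) for e in pred.edges} & gold_edges),
    )


def evaluate_predictions(
    gold_docs: list[AnnotatedDocument],
    pred_docs: list[AnnotatedDocument],
    eval_target: str = "closure",
) -> EvalReport:
    """Score predicted documents against gold.

    Entities are compared over the full mention sets; relations over
    gene-disease edges only (prediction output is gene-disease links), with
    gold taken raw or as the direct-edge closure.
    """
    gold_full = build_graph(gold_docs)
    pred_full = build_graph(pred_docs)
    ent = compare_graphs(gold_full, pred_full)
    gold_gd = build_graph(gold_docs, relation_scope="gene-disease", eval_target=eval_target)
    pred_gd = build_graph(pred_docs, relation_scope="gene-disease", eval_target="raw")
    rel = compare_graphs(gold_gd, pred_gd)
    return EvalReport(
        entity_tp=ent.entity_tp, entity_fp=ent.entity_fp, entity_fn=ent.entity_fn,
        relation_tp=rel.relation_tp, relation_fp=rel.relation_fp, relation_fn=rel.relation_fn,
    )


# ---------------------------------------------------------------------------
# Training wrappers

def make_model(cfg: TrainConfig, de_augment: bool | None = None, only_re: bool | None = None) -> JointExtractor:
    return JointExtractor(
        hidden=cfg.hidden, layers=cfg.layers, heads=cfg.heads,
        vocab_size=cfg.vocab_size, epochs=cfg.epochs, batch_size=cfg.batch_size,
        lr=cfg.lr, warmup=cfg.warmup, seq2seq=cfg.seq2seq, seed=cfg.seed,
        de_augment=cfg.de_augment if de_augment is None else de_augment,
        only_re=cfg.only_re if only_re is None else only_re,
    )


def train(corpus: list[AnnotatedDocument], cfg: TrainConfig) -> JointExtractor:
    """Fit one joint model on the whole corpus with the configured schedule."""
    if not corpus:
        raise ValueError("cannot train on an empty corpus")
    return make_model(cfg).fit(corpus)


def cross_validate(
    corpus: list[AnnotatedDocument],
    cfg: TrainConfig,
    de_augment: bool | None = None,
    only_re: bool | None = None,
) -> FoldSummary:
    """k-fold CV: train on k-1 folds (DE augmentation on training folds only),
    evaluate on the held-out fold against un-augmented gold."""
    folds = kfold_split(corpus, k=cfg.folds, seed=cfg.seed)
    summary = FoldSummary()
    for f in range(cfg.folds):
        train_docs = [d for g in range(cfg.folds) if g != f for d in folds[g]]
        model = make_model(cfg, de_augment=de_augment, only_re=only_re)
        model.fit(train_docs)
        preds = model.predict(folds[f])
        summary.reports.append(
            evaluate_predictions(folds[f], preds, eval_target=cfg.eval_target)
        )
    return summary


def ablation_run(
    corpus: list[AnnotatedDocument], cfg: TrainConfig
) -> dict[str, FoldSummary]:
    """Four CV arms over (+/-DE) x (joint / onlyRE) with identical folds.

    Fold assignment depends only on (corpus, cfg.folds, cfg.seed), so the
    arms are paired by construction and support per-fold comparisons.
    """
    arms = {}
    for de in (False, True):
        for only_re in (False, True):
            name = f"{'onlyRE' if only_re else 'joint'}_{'with' if de else 'no'}_de"
            arms[name] = cross_validate(corpus, cfg, de_augment=de, only_re=only_re)
    return arms
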