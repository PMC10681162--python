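"""Entity linking, decision-rule filtering and knowledge-graph integration.

Linking maps a mention surface to a dictionary identifier (genes: NCBI-Gene
style; diseases: EFO style — the loaders are format-only, the data is user
supplied) by cosine similarity over character-3-gram count vectors, served
by a nearest-neighbour index with an exhaustive option. Proteins link
against the gene namespace, receiving the identifier of the encoding gene's
entry.

Prediction graphs then pass through an ordered, registered set of decision
rules (probability threshold, unlinked-node drop, namespace whitelist,
degree cap), node merging (same identifier -> one node), trigger reduction
(trigger nodes removed, trigger-mediated gene/protein-disease connectivity
preserved as direct edges), and cross-document integration into one
bipartite gene-disease graph with per-edge provenance.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import networkx as nx
import numpy as np
from pydantic import BaseModel, Field
from scipy.sparse import csr_matrix
from sklearn.neighbors import NearestNeighbors

from gdlink.corpus_io import AnnotatedDocument

log = logging.getLogger(__name__)

#: Mention types carrying a gene-namespace identifier after linking.
GENE_NAMESPACE_TYPES = ("Gene", "Protein")


def char_3grams(s: str) -> Counter[str]:
    """Multiset of lowercased character 3-grams.

    Strings shorter than 3 characters yield a single padded gram
    (``^ab$``-style) so short gene symbols still get a non-empty profile;
    the empty string yields the empty multiset.
    """
    s = s.lower()
    if not s:
        return Counter()
    if len(s) < 3:
        return Counter([f"^{s}$"])
    return Counter(s[i : i + 3] for i in range(len(s) - 2))


@dataclass
class Dictionary:
    """Identifier dictionary for one namespace with cached 3-gram profiles."""

    namespace: str  # "gene" | "disease"
    entries: list[tuple[str, str, list[str]]]  # (identifier, name, synonyms)
    _gram_index: dict[str, int] = field(default_factory=dict, repr=False)
    _matrix: csr_matrix | None = field(default=None, repr=False)
    _row_ids: list[str] = field(default_factory=list, repr=False)
    _nn: NearestNeighbors | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate identifiers in {self.namespace} dictionary")
        self._build()

    def _build(self) -> None:
        rows: list[Counter[str]] = []
        for ident, name, synonyms in self.entries:
            for s in [name, *synonyms]:
                prof = char_3grams(s)
                if prof:
                    rows.append(prof)
                    self._row_ids.append(ident)
        for prof in rows:
            for g in prof:
                self._gram_index.setdefault(g, len(self._gram_index))
        if not rows:
            return
        data, indices, indptr = [], [], [0]
        for prof in rows:
            for g, c in sorted(prof.items()):
                indices.append(self._gram_index[g])
                data.append(float(c))
            indptr.append(len(indices))
        self._matrix = csr_matrix(
            (data, indices, indptr), shape=(len(rows), len(self._gram_index))
        )
        self._nn = NearestNeighbors(metric="cosine", algorithm="brute")
        self._nn.fit(self._matrix)

    def profile_vector(self, s: str) -> csr_matrix:
        prof = char_3grams(s)
        cols, vals = [], []
        for g, c in sorted(prof.items()):
            if g in self._gram_index:
                cols.append(self._gram_index[g])
                vals.append(float(c))
        return csr_matrix((vals, ([0] * len(cols), cols)), shape=(1, len(self._gram_index)))

    @classmethod
    def from_tsv(cls, path: str | Path, namespace: str) -> "Dictionary":
        """TSV rows: identifier, canonical name, then any number of synonyms."""
        entries = []
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                entries.append((row[0], row[1], [s for s in row[2:] if s]))
        return cls(namespace=namespace, entries=entries)


def link_entity(
    surface: str, dictionary: Dictionary, top_k: int = 5, min_sim: float = 0.7
) -> str | None:
    """Identifier of the most 3-gram-cosine-similar entry, or None.

    Returns None for empty dictionaries (with a warning), for surfaces
    sharing no 3-gram with any entry, and when the best similarity falls
    below ``min_sim``.
    """
    if dictionary._nn is None:
        log.warning("empty %s dictionary; every query links to None", dictionary.namespace)
        return None
    q = dictionary.profile_vector(surface)
    if q.nnz == 0:
        return None
    k = min(top_k, dictionary._matrix.shape[0])
    dist, idx = dictionary._nn.kneighbors(q, n_neighbors=k)
    best_sim = 1.0 - float(dist[0][0])
    if best_sim < min_sim:
        return None
    return dictionary._row_ids[int(idx[0][0])]


def link_document_graph(
    g: nx.Graph, gene_dict: Dictionary, disease_dict: Dictionary, min_sim: float = 0.7
) -> nx.Graph:
    """Attach an ``identifier`` attribute to every gene/protein/disease node."""
    g = g.copy()
    for n, attrs in g.nodes(data=True):
        et = attrs.get("etype")
        if et in GENE_NAMESPACE_TYPES:
            attrs["identifier"] = link_entity(attrs["surface"], gene_dict, min_sim=min_sim)
            attrs["namespace"] = "gene"
        elif et == "Disease":
            attrs["identifier"] = link_entity(attrs["surface"], disease_dict, min_sim=min_sim)
            attrs["namespace"] = "disease"
        else:
            attrs["identifier"] = None
            attrs["namespace"] = None
    return g


# ---------------------------------------------------------------------------
# Document graphs

def graph_from_document(
    doc: AnnotatedDocument, p_links: dict[tuple[str, str], float] | None = None
) -> nx.Graph:
    """Per-document knowledge graph: nodes are mentions, edges LinkedOf relations.

    Node keys are (doc_id, start, end, etype); every node and edge carries a
    provenance set of document ids, and edges carry the link probability
    when one is supplied.
    """
    g = nx.Graph()
    by_id = {m.id: m for m in doc.mentions}
    key = {m.id: (doc.doc_id, m.start, m.end, m.etype) for m in doc.mentions}
    for m in doc.mentions:
        g.add_node(key[m.id], etype=m.etype, surface=m.surface,
                   provenance={doc.doc_id}, identifier=None, namespace=None)
    for r in doc.relations:
        p = None
        if p_links is not None:
            p = p_links.get((r.e0, r.e1), p_links.get((r.e1, r.e0)))
        if key[r.e0] != key[r.e1]:
            g.add_edge(key[r.e0], key[r.e1], rtype=r.rtype,
                       provenance={doc.doc_id}, p_link=p)
    _ = by_id
    return g


# ---------------------------------------------------------------------------
# Decision rules

RuleFn = Callable[[nx.Graph, dict], nx.Graph]
_RULES: dict[str, RuleFn] = {}


def register_rule(name: str) -> Callable[[RuleFn], RuleFn]:
    def deco(fn: RuleFn) -> RuleFn:
        _RULES[name] = fn
        return fn
    return deco


@register_rule("min_p_link")
def _rule_min_p(g: nx.Graph, params: dict) -> nx.Graph:
    thr = params.get("threshold", 0.5)
    out = g.copy()
    drop = [e for e, p in nx.get_edge_attributes(g, "p_link").items()
            if p is not None and p < thr]
    out.remove_edges_from(drop)
    return out


@register_rule("drop_unlinked")
def _rule_drop_unlinked(g: nx.Graph, params: dict) -> nx.Graph:
    out = g.copy()
    out.remove_nodes_from([n for n, a in g.nodes(data=True) if a.get("identifier") is None])
    return out


@register_rule("namespace_whitelist")
def _rule_namespace(g: nx.Graph, params: dict) -> nx.Graph:
    allowed = set(params.get("etypes", []))
    out = g.copy()
    out.remove_nodes_from([n for n, a in g.nodes(data=True) if a.get("etype") not in allowed])
    return out


@register_rule("degree_cap")
def _rule_degree(g: nx.Graph, params: dict) -> nx.Graph:
    cap = params.get("max_degree", 50)
    out = g.copy()
    out.remove_nodes_from([n for n in g.nodes if g.degree(n) > cap])
    return out


class RuleConfig(BaseModel):
    """Ordered decision-rule pipeline; names must be registered filters."""

    rules: list[tuple[str, dict]] = Field(default_factory=list)


def apply_rules(g: nx.Graph, config: RuleConfig) -> nx.Graph:
    """Apply the configured filters in order; each logs its removal counts."""
    for name, params in config.rules:
        if name not in _RULES:
            raise KeyError(
                f"unknown decision rule {name!r}; registered: {sorted(_RULES)}"
            )
        before = (g.number_of_nodes(), g.number_of_edges())
        g = _RULES[name](g, params)
        after = (g.number_of_nodes(), g.number_of_edges())
        log.info("rule %s removed %d nodes, %d edges",
                 name, before[0] - after[0], before[1] - after[1])
    return g


# ---------------------------------------------------------------------------
# Merge / reduce / integrate

def _merged_key(attrs: dict, node) -> object:
    if attrs.get("identifier") is not None:
        return (attrs["namespace"], attrs["identifier"])
    return node


def merge_nodes(g: nx.Graph) -> nx.Graph:
    """Collapse nodes sharing a non-null (namespace, identifier); idempotent.

    Edges re-attach with provenance unioned and p_link maximized; self-loops
    produced by a merge are dropped.
    """
    out = nx.Graph()
    mapping = {n: _merged_key(a, n) for n, a in g.nodes(data=True)}
    for n, a in g.nodes(data=True):
        k = mapping[n]
        if k in out:
            out.nodes[k]["provenance"] = out.nodes[k]["provenance"] | a["provenance"]
            out.nodes[k].setdefault("surfaces", set()).add(a["surface"])
        else:
            out.add_node(k, **{**a, "provenance": set(a["provenance"]),
                               "surfaces": {a["surface"]}})
    for u, v, a in g.edges(data=True):
        ku, kv = mapping[u], mapping[v]
        if ku == kv:
            continue
        if out.has_edge(ku, kv):
            e = out.edges[ku, kv]
            e["provenance"] = e["provenance"] | a["provenance"]
            if a.get("p_link") is not None:
                e["p_link"] = max(p for p in (e.get("p_link"), a["p_link"]) if p is not None)
        else:
            out.add_edge(ku, kv, **{**a, "provenance": set(a["provenance"])})
    return out


def reduce_triggers(g: nx.Graph) -> nx.Graph:
    """Remove trigger nodes, preserving gene/protein-disease connectivity.

    Endpoint pairs connected through any path interior to trigger nodes get
    a direct edge whose provenance is the union over the path's nodes and
    edges. Idempotent; a graph without trigger nodes is returned unchanged.
    """
    is_endpoint = {
        n: a.get("etype") in GENE_NAMESPACE_TYPES + ("Disease",)
        for n, a in g.nodes(data=True)
    }
    triggers = [n for n in g.nodes if not is_endpoint[n]]
    out = g.copy()
    if not triggers:
        return out
    trig_sub = g.subgraph(triggers)
    for comp in nx.connected_components(trig_sub):
        # Endpoints adjacent to this trigger component.
        prov: set = set()
        for t in comp:
            prov |= g.nodes[t]["provenance"]
        attached: list = []
        for t in comp:
            for nb in g.neighbors(t):
                if is_endpoint[nb]:
                    attached.append(nb)
                    prov |= g.edges[t, nb]["provenance"]
        gene_side = [n for n in set(attached) if g.nodes[n].get("etype") in GENE_NAMESPACE_TYPES]
        dis_side = [n for n in set(attached) if g.nodes[n].get("etype") == "Disease"]
        for u in gene_side:
            for v in dis_side:
                if out.has_edge(u, v):
                    out.edges[u, v]["provenance"] = out.edges[u, v]["provenance"] | prov
                else:
                    out.add_edge(u, v, rtype="LinkedOf", provenance=set(prov), p_link=None)
    out.remove_nodes_from(triggers)
    return out


def integrate(graphs: Iterable[nx.Graph]) -> nx.Graph:
    """Union per-document graphs into one bipartite gene-disease graph.

    Each input is merged and trigger-reduced first (making the call safe on
    raw document graphs), then nodes are unified across documents at the
    identifier level (unlinked nodes fall back to lowercased-surface
    identity within their namespace). Edge provenance lists every
    contributing document; per-edge probability keeps the maximum.
    Order-independent up to isomorphism.
    """
    out = nx.Graph()
    for g in graphs:
        h = merge_nodes(reduce_triggers(g))
        mapping = {}
        for n, a in h.nodes(data=True):
            if a.get("namespace") is None:
                continue  # residual non-endpoint node
            if a.get("identifier") is not None:
                mapping[n] = (a["namespace"], a["identifier"])
            else:
                surf = min(a.get("surfaces", {a.get("surface", "")}))
                mapping[n] = (a["namespace"], f"unlinked:{surf.lower()}")
        for n, a in h.nodes(data=True):
            if n not in mapping:
                continue
            k = mapping[n]
            if k in out:
                out.nodes[k]["provenance"] |= a["provenance"]
                out.nodes[k]["surfaces"] |= a.get("surfaces", {a.get("surface", "")})
            else:
                out.add_node(k, namespace=k[0], identifier=a.get("identifier"),
                             etype=a.get("etype"),
                             provenance=set(a["provenance"]),
                             surfaces=set(a.get("surfaces", {a.get("surface", "")})))
        for u, v, a in h.edges(data=True):
            if u not in mapping or v not in mapping:
                continue
            ku, kv = mapping[u], mapping[v]
            if ku == kv:
                continue
            if {out.nodes[ku]["namespace"], out.nodes[kv]["namespace"]} != {"gene", "disease"}:
                continue  # keep the integrated graph bipartite
            if out.has_edge(ku, kv):
                e = out.edges[ku, kv]
                e["provenance"] = e["provenance"] | a["provenance"]
                ps = [p for p in (e.get("p_link"), a.get("p_link")) if p is not None]
                e["p_link"] = max(ps) if ps else None
            else:
                out.add_edge(ku, kv, rtype="LinkedOf",
                             provenance=set(a["provenance"]), p_link=a.get("p_link"))
    return out


# ---------------------------------------------------------------------------
# Export

def export_edge_tsv(g: nx.Graph, path: str | Path) -> None:
    """TSV edge list: gene_id, disease_id, n_docs, doc_ids, max_p_link."""
    rows = []
    for u, v, a in g.edges(data=True):
        gene, dis = (u, v) if g.nodes[u].get("namespace") == "gene" else (v, u)
        prov = sorted(a.get("provenance", set()))
        rows.append((str(gene[1]), str(dis[1]), len(prov), ",".join(prov),
                     "" if a.get("p_link") is None else f"{a['p_link']:.4f}"))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["gene_id", "disease_id", "n_docs", "doc_ids", "max_p_link"])
        for row in sorted(rows):
            w.writerow(row)


def export_node_link_json(g: nx.Graph) -> dict:
    """JSON-serializable node-link dump (sets become sorted lists)."""
    h = nx.Graph()
    for n, a in g.nodes(data=True):
        h.add_node(str(n), **{k: sorted(v) if isinstance(v, set) else v for k, v in a.items()})
    for u, v, a in g.edges(data=True):
        h.add_edge(str(u), str(v), **{k: sorted(x) if isinstance(x, set) else x
                                      for k, x in a.items()})
    return nx.node_link_data(h, edges="links")
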