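"""Char-3-gram linking, decision rules, merge/reduce/integrate."""

import itertools
from collections import Counter

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gdlink.corpus_io import RelationInstance
from gdlink.linking import (
    Dictionary,
    RuleConfig,
    apply_rules,
    char_3grams,
    graph_from_document,
    integrate,
    link_document_graph,
    link_entity,
    merge_nodes,
    reduce_triggers,
)
from tests.conftest import make_doc


class TestChar3Grams:
    def test_brca1(self):
        assert char_3grams("BRCA1") == Counter({"brc": 1, "rca": 1, "ca1": 1})

    def test_empty_string(self):
        assert char_3grams("") == Counter()

    def test_multiset_semantics(self):
        assert char_3grams("aaaa") == Counter({"aaa": 2})

    def test_short_string_padded_single_gram(self):
        assert char_3grams("AR") == Counter({"^ar$": 1})
        assert sum(char_3grams("AR").values()) == 1


@pytest.fixture
def gene_dict() -> Dictionary:
    return Dictionary(namespace="gene", entries=[
        ("NCBI:672", "BRCA1", ["breast cancer 1"]),
        ("NCBI:7157", "TP53", ["tumor protein p53"]),
        ("NCBI:3845", "KRAS", []),
    ])


def brute_force_best(surface: str, entries) -> tuple[str | None, float]:
    """Exhaustive cosine over 3-gram count vectors (independent oracle)."""
    q = char_3grams(surface)
    best, best_sim = None, -1.0
    for ident, name, synonyms in entries:
        for s in [name, *synonyms]:
            p = char_3grams(s)
            grams = set(q) | set(p)
            dot = sum(q[g] * p[g] for g in grams)
            nq = np.sqrt(sum(v * v for v in q.values()))
            np_ = np.sqrt(sum(v * v for v in p.values()))
            sim = dot / (nq * np_) if nq and np_ else 0.0
            if sim > best_sim:
                best, best_sim = ident, sim
    return best, best_sim


class TestLinkEntity:
    def test_exact_canonical_name_links(self, gene_dict):
        assert link_entity("BRCA1", gene_dict) == "NCBI:672"

    def test_no_shared_grams_gives_none(self, gene_dict):
        assert link_entity("zzzzz", gene_dict) is None

    def test_below_min_sim_gives_none(self, gene_dict):
        assert link_entity("BRCA-like-thing", gene_dict, min_sim=0.99) is None

    def test_variant_spelling_matches_brute_force_ranking(self, gene_dict):
        oracle_id, oracle_sim = brute_force_best("BRCA-1", gene_dict.entries)
        got = link_entity("BRCA-1", gene_dict, min_sim=0.0)
        assert got == oracle_id
        assert oracle_sim > 0

    def test_empty_dictionary_links_none_with_warning(self, caplog):
        empty = Dictionary(namespace="gene", entries=[])
        with caplog.at_level("WARNING"):
            assert link_entity("BRCA1", empty) is None

    @pytest.mark.parametrize("query", [
        "BRCA1", "brca 1", "TP53", "p53 tumor protein", "KRAS", "KRAS2",
        "breast cancer one", "tumor", "protein p53",
    ])
    def test_agrees_with_exhaustive_search(self, gene_dict, query):
        oracle_id, oracle_sim = brute_force_best(query, gene_dict.entries)
        got = link_entity(query, gene_dict, min_sim=0.0)
        if got != oracle_id:
            # acceptable only on exact similarity ties
            got_sim = brute_force_best(query, [e for e in gene_dict.entries if e[0] == got])[1]
            assert got_sim == pytest.approx(oracle_sim, abs=1e-9)

    def test_tsv_loader(self, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text("#id\tname\tsyn\nNCBI:672\tBRCA1\tbreast cancer 1\nNCBI:3845\tKRAS\n")
        d = Dictionary.from_tsv(p, "gene")
        assert link_entity("KRAS", d) == "NCBI:3845"


def two_doc_graphs():
    """Two documents naming the same gene with different diseases."""
    d1 = make_doc("p1", "TP53 inhibits melanoma",
                  [("g", 0, 4, "Gene"), ("t", 5, 13, "NegReg"), ("d", 14, 22, "Disease")],
                  [("g", "t"), ("t", "d")])
    d2 = make_doc("p2", "TP53 promotes leukemia",
                  [("g", 0, 4, "Gene"), ("t", 5, 13, "PosReg"), ("d", 14, 22, "Disease")],
                  [("g", "t"), ("t", "d")])
    gene_dict = Dictionary(namespace="gene", entries=[("NCBI:7157", "TP53", [])])
    dis_dict = Dictionary(namespace="disease", entries=[
        ("EFO:0000756", "melanoma", []), ("EFO:0000565", "leukemia", [])])
    graphs = []
    for d in (d1, d2):
        g = graph_from_document(d)
        graphs.append(link_document_graph(g, gene_dict, dis_dict))
    return graphs


class TestRules:
    def make_graph(self):
        g = nx.Graph()
        g.add_node("a", etype="Gene", surface="TP53", identifier="NCBI:7157",
                   namespace="gene", provenance={"p1"})
        g.add_node("b", etype="Disease", surface="melanoma", identifier=None,
                   namespace="disease", provenance={"p1"})
        g.add_node("c", etype="Disease", surface="leukemia", identifier="EFO:1",
                   namespace="disease", provenance={"p1"})
        g.add_edge("a", "b", p_link=0.95, provenance={"p1"})
        g.add_edge("a", "c", p_link=0.5, provenance={"p1"})
        return g

    def test_empty_rule_list_is_identity(self):
        g = self.make_graph()
        out = apply_rules(g, RuleConfig())
        assert set(out.nodes) == set(g.nodes) and set(out.edges) == set(g.edges)

    def test_min_p_link_threshold(self):
        out = apply_rules(self.make_graph(),
                          RuleConfig(rules=[("min_p_link", {"threshold": 0.9})]))
        assert out.number_of_edges() == 1

    def test_drop_unlinked_removes_node_and_edges(self):
        out = apply_rules(self.make_graph(), RuleConfig(rules=[("drop_unlinked", {})]))
        assert "b" not in out.nodes
        assert out.number_of_edges() == 1

    def test_unknown_rule_raises(self):
        with pytest.raises(KeyError, match="no_such_rule"):
            apply_rules(self.make_graph(), RuleConfig(rules=[("no_such_rule", {})]))


class TestMergeNodes:
    def test_same_identifier_nodes_merge_with_edges(self):
        g = nx.Graph()
        for i, dis in enumerate(["melanoma", "leukemia"]):
            g.add_node(f"tp53-{i}", etype="Gene", surface="TP53",
                       identifier="NCBI:7157", namespace="gene", provenance={f"p{i}"})
            g.add_node(f"dis-{i}", etype="Disease", surface=dis,
                       identifier=f"EFO:{i}", namespace="disease", provenance={f"p{i}"})
            g.add_edge(f"tp53-{i}", f"dis-{i}", provenance={f"p{i}"}, p_link=0.9)
        out = merge_nodes(g)
        assert out.number_of_nodes() == 3
        gene_node = ("gene", "NCBI:7157")
        assert out.degree(gene_node) == 2
        assert out.nodes[gene_node]["provenance"] == {"p0", "p1"}

    def test_no_shared_identifiers_is_identity_on_structure(self):
        g = two_doc_graphs()[0]
        out = merge_nodes(g)
        assert out.number_of_nodes() == g.number_of_nodes()
        assert out.number_of_edges() == g.number_of_edges()

    def test_idempotent(self):
        g = two_doc_graphs()[0]
        once = merge_nodes(g)
        twice = merge_nodes(once)
        assert set(once.nodes) == set(twice.nodes)
        assert set(map(frozenset, once.edges)) == set(map(frozenset, twice.edges))


class TestReduceTriggers:
    def test_single_trigger_path_becomes_direct_edge(self):
        g = two_doc_graphs()[0]
        out = reduce_triggers(g)
        etypes = {a["etype"] for _, a in out.nodes(data=True)}
        assert etypes <= {"Gene", "Disease", "Protein"}
        assert out.number_of_edges() == 1

    def test_no_triggers_identity(self):
        g = nx.Graph()
        g.add_node("a", etype="Gene", surface="x", provenance={"p"}, identifier=None)
        g.add_node("b", etype="Disease", surface="y", provenance={"p"}, identifier=None)
        g.add_edge("a", "b", provenance={"p"})
        out = reduce_triggers(g)
        assert set(out.nodes) == {"a", "b"} and out.number_of_edges() == 1

    def test_two_trigger_chain_transitively_reduced(self):
        doc = make_doc(
            "d", "BRCA1 modulates apoptosis melanoma",
            [("g", 0, 5, "Gene"), ("t1", 6, 15, "Regulation"), ("t2", 16, 25, "MPA"),
             ("dd", 26, 34, "Disease")],
            [("g", "t1"), ("t1", "t2"), ("t2", "dd")],
        )
        out = reduce_triggers(graph_from_document(doc))
        assert out.number_of_edges() == 1
        (u, v), = out.edges
        assert {out.nodes[u]["etype"], out.nodes[v]["etype"]} == {"Gene", "Disease"}

    def test_idempotent(self):
        g = two_doc_graphs()[1]
        once = reduce_triggers(g)
        twice = reduce_triggers(once)
        assert set(once.nodes) == set(twice.nodes)
        assert set(map(frozenset, once.edges)) == set(map(frozenset, twice.edges))

    @settings(max_examples=40, deadline=None)
    @given(st.data())
    def test_matches_trigger_interior_connectivity_oracle(self, data):
        n = data.draw(st.integers(2, 8))
        types = data.draw(st.lists(st.sampled_from(["Gene", "Disease", "Regulation", "MPA"]),
                                   min_size=n, max_size=n))
        g = nx.Graph()
        for i, t in enumerate(types):
            g.add_node(i, etype=t, surface=f"s{i}", provenance={"p"}, identifier=None,
                       namespace=None)
        pairs = list(itertools.combinations(range(n), 2))
        for a, b in data.draw(st.lists(st.sampled_from(pairs), max_size=10, unique=True)):
            g.add_edge(a, b, provenance={"p"})
        out = reduce_triggers(g)
        endpoint = lambda i: types[i] in ("Gene", "Disease", "Protein")  # noqa: E731

        # Oracle: brute-force simple paths with all-trigger interiors.
        def connected_via_triggers(u, v):
            if g.has_edge(u, v):
                return True
            for path in nx.all_simple_paths(g, u, v, cutoff=n):
                if all(not endpoint(x) for x in path[1:-1]):
                    return True
            return False

        genes = [i for i in range(n) if types[i] == "Gene"]
        diseases = [i for i in range(n) if types[i] == "Disease"]
        for u in genes:
            for v in diseases:
                assert out.has_edge(u, v) == connected_via_triggers(u, v)


class TestIntegrate:
    def test_shared_gene_two_diseases(self):
        out = integrate(two_doc_graphs())
        gene_nodes = [nk for nk in out.nodes if nk[0] == "gene"]
        assert gene_nodes == [("gene", "NCBI:7157")]
        assert out.degree(("gene", "NCBI:7157")) == 2
        provs = {frozenset(a["provenance"]) for _, _, a in out.edges(data=True)}
        assert provs == {frozenset({"p1"}), frozenset({"p2"})}

    def test_single_document_consistency(self):
        g = two_doc_graphs()[0]
        solo = integrate([g])
        reduced = merge_nodes(reduce_triggers(g))
        assert solo.number_of_edges() == reduced.number_of_edges() == 1

    def test_bipartite_over_gene_disease(self):
        out = integrate(two_doc_graphs())
        for u, v in out.edges:
            assert {out.nodes[u]["namespace"], out.nodes[v]["namespace"]} == {"gene", "disease"}

    def test_order_independent(self):
        graphs = two_doc_graphs()
        a = integrate(graphs)
        b = integrate(list(reversed(graphs)))
        assert set(a.nodes) == set(b.nodes)
        assert set(map(frozenset, a.edges)) == set(map(frozenset, b.edges))
        for u, v in a.edges:
            assert a.edges[u, v]["provenance"] == b.edges[u, v]["provenance"]
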