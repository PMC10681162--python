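"""Standoff I/O, schema normalization and direct-edge augmentation."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from gdlink.corpus_io import (
    CorpusError,
    EntityMention,
    RelationInstance,
    SchemaMap,
    add_direct_edges,
    corpus_stats,
    normalize_schema,
    read_corpus,
    write_corpus,
)
from tests.conftest import make_doc


class TestReadWrite:
    def test_minimal_document_parses(self, tmp_path):
        (tmp_path / "d.json").write_text(
            '{"id": "d", "text": "BRCA1 causes cancer",'
            ' "denotations": [{"id": "a", "span": {"begin": 0, "end": 5}, "obj": "Gene"},'
            '                 {"id": "b", "span": {"begin": 13, "end": 19}, "obj": "Disease"}],'
            ' "relations": [{"id": "r", "subj": "a", "obj": "b", "pred": "LinkedOf"}]}'
        )
        docs = read_corpus(tmp_path / "d.json")
        assert len(docs) == 1
        assert len(docs[0].mentions) == 2
        assert len(docs[0].relations) == 1
        assert docs[0].mentions[0].surface == "BRCA1"

    def test_span_past_text_end_rejected(self, tmp_path):
        (tmp_path / "d.json").write_text(
            '{"id": "d", "text": "short",'
            ' "denotations": [{"id": "a", "span": {"begin": 0, "end": 99}, "obj": "Gene"}]}'
        )
        with pytest.raises(CorpusError, match="d.json"):
            read_corpus(tmp_path / "d.json")

    def test_invalid_json_names_file(self, tmp_path):
        (tmp_path / "bad.json").write_text("{not json")
        with pytest.raises(CorpusError, match="bad.json"):
            read_corpus(tmp_path)

    def test_round_trip_identity(self, tmp_path, trigger_doc):
        docs = [trigger_doc]
        write_corpus(docs, tmp_path / "c.json")
        assert read_corpus(tmp_path / "c.json") == docs

    def test_duplicate_triples_deduplicated_at_read(self, tmp_path):
        (tmp_path / "d.json").write_text(
            '{"id": "d", "text": "BRCA1 causes cancer",'
            ' "denotations": [{"id": "a", "span": {"begin": 0, "end": 5}, "obj": "Gene"},'
            '                 {"id": "b", "span": {"begin": 13, "end": 19}, "obj": "Disease"}],'
            ' "relations": [{"id": "r1", "subj": "a", "obj": "b", "pred": "LinkedOf"},'
            '               {"id": "r2", "subj": "a", "obj": "b", "pred": "LinkedOf"}]}'
        )
        (doc,) = read_corpus(tmp_path / "d.json")
        assert len(doc.relations) == 1


class TestValidation:
    def test_surface_mismatch_rejected(self):
        from gdlink.corpus_io import AnnotatedDocument

        m = EntityMention(id="a", doc_id="d", start=0, end=5, etype="Gene", surface="nope!")
        with pytest.raises(ValueError, match="surface"):
            AnnotatedDocument(doc_id="d", text="hello world", mentions=[m])

    def test_unknown_entity_type_rejected(self):
        with pytest.raises(ValueError, match="unknown entity type"):
            EntityMention(id="a", doc_id="d", start=0, end=3, etype="Foo", surface="abc")

    def test_self_relation_rejected(self):
        with pytest.raises(ValueError, match="self-relation"):
            RelationInstance(e0="a", e1="a")

    def test_dangling_relation_endpoint_rejected(self):
        with pytest.raises(ValueError, match="does not resolve"):
            make_doc("d", "BRCA1", [("a", 0, 5, "Gene")], [("a", "ghost")])


class TestNormalizeSchema:
    def test_agac_predicates_map_to_linkedof(self):
        doc = make_doc(
            "d", "BRCA1 upregulates melanoma",
            [("a", 0, 5, "Gene"), ("b", 6, 17, "PosReg"), ("c", 18, 26, "Disease")],
        )
        doc = doc.model_copy(update={"relations": [
            RelationInstance(e0="a", e1="b", rtype="ThemeOf"),
            RelationInstance(e0="b", e1="c", rtype="CauseOf"),
        ]})
        out = normalize_schema(doc)
        assert [r.rtype for r in out.relations] == ["LinkedOf", "LinkedOf"]

    def test_canonical_document_unchanged(self, trigger_doc):
        assert normalize_schema(trigger_doc) == trigger_doc

    def test_now_identical_triples_collapse(self):
        doc = make_doc("d", "BRCA1 melanoma", [("a", 0, 5, "Gene"), ("b", 6, 14, "Disease")])
        doc = doc.model_copy(update={"relations": [
            RelationInstance(e0="a", e1="b", rtype="ThemeOf"),
            RelationInstance(e0="a", e1="b", rtype="CauseOf"),
        ]})
        out = normalize_schema(doc)
        assert {r.key() for r in out.relations} == {("a", "b", "LinkedOf")}

    def test_unmapped_label_raises(self, trigger_doc):
        doc = trigger_doc.model_copy(update={"relations": [
            RelationInstance(e0="g", e1="t", rtype="Mystery")
        ]})
        with pytest.raises(CorpusError, match="Mystery"):
            normalize_schema(doc, SchemaMap())

    def test_mention_set_preserved(self, trigger_doc):
        assert normalize_schema(trigger_doc).mentions == trigger_doc.mentions


def brute_force_de_pairs(doc, endpoints=("Gene", "Disease")):
    """Oracle: enumerate all simple paths; keep gene-disease pairs whose
    interior nodes are all non-endpoint (trigger) mentions."""
    by_id = {m.id: m for m in doc.mentions}
    adj = {m.id: set() for m in doc.mentions}
    for r in doc.relations:
        adj[r.e0].add(r.e1)
        adj[r.e1].add(r.e0)
    genes = [m.id for m in doc.mentions if m.etype == "Gene"]
    diseases = [m.id for m in doc.mentions if m.etype == "Disease"]
    found = set()

    def dfs(path, target):
        last = path[-1]
        if last == target:
            if all(by_id[x].etype not in endpoints for x in path[1:-1]):
                found.add((path[0], target))
            return
        for nxt in adj[last]:
            if nxt in path:
                continue
            if nxt != target and by_id[nxt].etype in endpoints:
                continue
            dfs(path + [nxt], target)

    for g in genes:
        for d in diseases:
            dfs([g], d)
    return found


class TestDirectEdges:
    def test_single_trigger_path_gets_direct_edge(self, trigger_doc):
        out = add_direct_edges(trigger_doc)
        direct = [r for r in out.relations if r.direct]
        assert [(r.e0, r.e1) for r in direct] == [("g", "d")]

    def test_no_disease_means_unchanged(self):
        doc = make_doc("d", "BRCA1 upregulates",
                       [("g", 0, 5, "Gene"), ("t", 6, 17, "PosReg")], [("g", "t")])
        assert add_direct_edges(doc) == doc

    def test_two_trigger_chain_and_bystander_gene(self):
        text = "BRCA1 modulates apoptosis melanoma KRAS"
        doc = make_doc(
            "d", text,
            [("g", 0, 5, "Gene"), ("t1", 6, 15, "Regulation"), ("t2", 16, 25, "MPA"),
             ("d", 26, 34, "Disease"), ("g2", 35, 39, "Gene")],
            [("g", "t1"), ("t1", "t2"), ("t2", "d")],
        )
        out = add_direct_edges(doc)
        new = {(r.e0, r.e1) for r in out.relations if r.direct}
        assert new == {("g", "d")}

    def test_gene_interior_blocks_path(self):
        # g - g2 - d: the interior node is a Gene, so no direct edge.
        text = "BRCA1 KRAS melanoma"
        doc = make_doc(
            "d", text,
            [("g", 0, 5, "Gene"), ("g2", 6, 10, "Gene"), ("d", 11, 19, "Disease")],
            [("g", "g2"), ("g2", "d")],
        )
        assert not [r for r in add_direct_edges(doc).relations if r.direct]

    def test_idempotent_and_monotone(self, trigger_doc):
        once = add_direct_edges(trigger_doc)
        twice = add_direct_edges(once)
        assert once == twice
        assert {r.key() for r in trigger_doc.relations} <= {r.key() for r in once.relations}

    @settings(max_examples=40, deadline=None)
    @given(st.data())
    def test_matches_brute_force_path_oracle(self, data):
        n = data.draw(st.integers(3, 7))
        types = data.draw(st.lists(
            st.sampled_from(["Gene", "Disease", "Regulation", "MPA", "Protein"]),
            min_size=n, max_size=n))
        words = [f"w{i}" for i in range(n)]
        text = " ".join(words)
        mentions, pos = [], 0
        for i, t in enumerate(types):
            mentions.append((f"m{i}", pos, pos + len(words[i]), t))
            pos += len(words[i]) + 1
        all_pairs = list(itertools.combinations(range(n), 2))
        chosen = data.draw(st.lists(st.sampled_from(all_pairs), max_size=n + 2, unique=True))
        doc = make_doc("d", text, mentions, [(f"m{a}", f"m{b}") for a, b in chosen])
        out = add_direct_edges(doc)
        got = {(r.e0, r.e1) for r in out.relations if r.direct}
        existing = {(r.e0, r.e1) for r in doc.relations} | {
            (r.e1, r.e0) for r in doc.relations}
        expected = {p for p in brute_force_de_pairs(doc) if p not in existing}
        assert got == expected


class TestCorpusStats:
    def test_empty_corpus_all_zero(self):
        assert corpus_stats([]) == {
            "documents": 0, "entities": 0, "relations": 0, "entities_by_type": {}}

    def test_totals_are_additive(self, trigger_doc):
        doc2 = make_doc("d2", "KRAS melanoma",
                        [("a", 0, 4, "Gene"), ("b", 5, 13, "Disease")], [("a", "b")])
        stats = corpus_stats([trigger_doc, doc2])
        assert stats["entities"] == 5
        assert stats["relations"] == 3
        assert stats["documents"] == 2
        assert sum(stats["entities_by_type"].values()) == stats["entities"]
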