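"""Seeded synthetic annotated corpora with trigger-mediated gene-disease links.

The generator emulates the statistical structure of a document-level
gene-disease annotation corpus: 12 entity types in two categories,
gene+disease mentions making up roughly 40% of all entities, relations
annotated through trigger words (Gene -> trigger -> Disease, with occasional
two-trigger chains), and a fraction of negative documents carrying no
relations at all.

Surface realization is deliberately simple (per-type lexicons embedded in
filler text) but includes two hard cases on purpose: a few surface forms
shared between types, so a lookup table cannot solve NER, and an optional
held-out lexicon split so evaluation documents contain unseen surfaces.
The generator records the gene-disease pairs it intends to be linked, which
downstream tests use as bookkeeping for direct-edge augmentation.

Linked gene-disease pairs appear in one sentence in the stereotyped pattern
``<gene> <trigger> <disease>``; unlinked genes and diseases never share a
sentence with an intervening trigger, so the between-tokens max-pool and
the attention context carry real signal.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, Field

from gdlink.corpus_io import (
    ENTITY_TYPES,
    LINKED_OF,
    AnnotatedDocument,
    EntityMention,
    RelationInstance,
)

# Per-type lexicons. Multi-token surfaces are common, and a few entries are
# deliberately ambiguous across types ("p53 signal" Pathway vs "p53" Gene
# context decides). Each list is split in half for train/heldout use.
_LEXICONS: dict[str, list[str]] = {
    "Gene": [
        "BRCA1", "TP53", "EGFR", "KRAS", "MYC", "PTEN", "ALK", "BRAF",
        "CDK4", "NOTCH1", "JAK2", "FLT3", "RB1", "APC", "VHL", "MET",
    ],
    "Disease": [
        "breast cancer", "lung carcinoma", "melanoma", "leukemia",
        "glioblastoma", "colorectal cancer", "lymphoma", "osteosarcoma",
        "pancreatic cancer", "ovarian cancer", "gastric cancer", "myeloma",
    ],
    "Protein": [
        "p53 protein", "kinase domain", "receptor complex", "cyclin D1",
        "beta catenin", "growth factor", "ligase subunit", "caspase 3",
    ],
    "Variation": [
        "V600E mutation", "exon 19 deletion", "T790M variant", "frameshift",
        "missense change", "G12D substitution", "splice variant", "amplification",
    ],
    "Enzyme": [
        "kinase", "phosphatase", "methyltransferase", "helicase",
        "polymerase", "protease", "ligase", "deacetylase",
    ],
    "MPA": [
        "phosphorylation", "apoptosis", "methylation", "transcription",
        "autophagy", "ubiquitination", "glycolysis", "translation",
    ],
    "CPA": [
        "proliferation", "migration", "invasion", "differentiation",
        "angiogenesis", "senescence", "adhesion", "metastasis",
    ],
    "Interaction": [
        "binding", "dimerization", "complex formation", "recruitment",
        "association", "crosstalk", "docking", "tethering",
    ],
    "Pathway": [
        "MAPK pathway", "PI3K signaling", "WNT cascade", "p53 signal",
        "NOTCH axis", "JAK STAT route", "mTOR signaling", "hedgehog pathway",
    ],
    "Regulation": [
        "modulates", "regulates", "controls", "influences",
        "affects", "alters", "governs", "shapes",
    ],
    "PosReg": [
        "activates", "upregulates", "promotes", "enhances",
        "induces", "drives", "stimulates", "amplifies",
    ],
    "NegReg": [
        "inhibits", "suppresses", "represses", "silences",
        "blocks", "attenuates", "downregulates", "impairs",
    ],
}

_FILLER = [
    "the", "study", "shows", "that", "in", "patients", "observed",
    "analysis", "of", "samples", "revealed", "expression", "levels",
    "were", "measured", "across", "cohorts", "with", "notable", "results",
]

_TRIGGER_TYPES = ("Regulation", "PosReg", "NegReg")
_OTHER_TYPES = ("Protein", "Variation", "Enzyme", "MPA", "CPA", "Interaction", "Pathway")

# Unannotated connectives used for directly annotated gene-disease links;
# disjoint from every lexicon so the two link patterns stay distinguishable.
_CONNECTIVES = ["is associated with", "is linked to", "is implicated in"]


class SynthConfig(BaseModel):
    """Generation parameters; same (config, seed) gives a byte-identical corpus."""

    n_docs: int = 100
    seed: int = 0
    sentences_per_doc: tuple[int, int] = (2, 4)
    entity_rate: float = 2.5  # expected mentions per sentence beyond the relation patterns
    gene_disease_fraction: float = 0.4
    relation_rate: float = 1.5  # expected links per positive document
    negative_doc_fraction: float = 0.2
    two_trigger_fraction: float = 0.2  # of trigger links realized as g-t1-t2-d chains
    direct_link_fraction: float = 0.5  # of links annotated as direct g-d edges
    lexicon_split: str = "all"  # "all" | "train" | "heldout"
    vocab: dict[str, list[str]] = Field(default_factory=lambda: dict(_LEXICONS))

    def lexicon(self, etype: str) -> list[str]:
        entries = self.vocab.get(etype, [])
        if not entries:
            raise ValueError(f"empty lexicon for entity type {etype!r}")
        half = max(1, len(entries) // 2)
        if self.lexicon_split == "train":
            return entries[:half]
        if self.lexicon_split == "heldout":
            return entries[half:]
        return entries


class _DocBuilder:
    """Accumulates words and mention annotations for one document."""

    def __init__(self, doc_id: str) -> None:
        self.doc_id = doc_id
        self.words: list[str] = []
        self.mentions: list[EntityMention] = []
        self.relations: list[RelationInstance] = []
        self._mid = 0

    def add_word(self, w: str) -> None:
        self.words.append(w)

    def add_mention(self, surface: str, etype: str) -> str:
        start = sum(len(w) + 1 for w in self.words)
        self.words.extend(surface.split(" "))
        mid = f"T{self._mid}"
        self._mid += 1
        self.mentions.append(
            EntityMention(
                id=mid, doc_id=self.doc_id, start=start,
                end=start + len(surface), etype=etype, surface=surface,
            )
        )
        return mid

    def build(self) -> AnnotatedDocument:
        return AnnotatedDocument(
            doc_id=self.doc_id,
            text=" ".join(self.words),
            mentions=self.mentions,
            relations=self.relations,
        ).dedup_relations()


def _doc_rng(seed: int, i: int) -> np.random.Generator:
    # Substream per document so corpora are stable under doc reordering.
    return np.random.default_rng(np.random.SeedSequence([seed, i]))


def _pick(rng: np.random.Generator, items: list[str]) -> str:
    return items[int(rng.integers(len(items)))]


def _generate_doc(cfg: SynthConfig, i: int) -> tuple[AnnotatedDocument, list[tuple[str, str]]]:
    rng = _doc_rng(cfg.seed, i)
    b = _DocBuilder(f"synth-{cfg.seed}-{i}")
    negative = rng.random() < cfg.negative_doc_fraction
    n_sent = int(rng.integers(cfg.sentences_per_doc[0], cfg.sentences_per_doc[1] + 1))
    n_links = 0 if negative else max(1, int(rng.poisson(cfg.relation_rate)))
    link_sents = set(rng.choice(n_sent, size=min(n_links, n_sent), replace=False).tolist())
    gd_pairs: list[tuple[str, str]] = []

    for s in range(n_sent):
        b.add_word(_pick(rng, _FILLER).capitalize())
        if s in link_sents:
            if rng.random() < cfg.direct_link_fraction:
                # Directly annotated link: "<gene> is associated with <disease>".
                g = b.add_mention(_pick(rng, cfg.lexicon("Gene")), "Gene")
                for w in _pick(rng, _CONNECTIVES).split(" "):
                    b.add_word(w)
                d = b.add_mention(_pick(rng, cfg.lexicon("Disease")), "Disease")
                b.relations.append(
                    RelationInstance(e0=g, e1=d, rtype=LINKED_OF, direct=True)
                )
            else:
                # Trigger-mediated link: gene [trigger [trigger]] disease.
                g = b.add_mention(_pick(rng, cfg.lexicon("Gene")), "Gene")
                triggers = []
                n_trig = 2 if rng.random() < cfg.two_trigger_fraction else 1
                for k in range(n_trig):
                    ttype = _pick(rng, list(_TRIGGER_TYPES))
                    triggers.append(b.add_mention(_pick(rng, cfg.lexicon(ttype)), ttype))
                    if k < n_trig - 1:
                        b.add_word(_pick(rng, _FILLER))
                d = b.add_mention(_pick(rng, cfg.lexicon("Disease")), "Disease")
                chain = [g, *triggers, d]
                for u, v in zip(chain, chain[1:]):
                    b.relations.append(RelationInstance(e0=u, e1=v, rtype=LINKED_OF))
            gd_pairs.append((g, d))
        # Background mentions and filler. Type mix honors gene_disease_fraction;
        # background genes/diseases go in trigger-free sentences only, so they
        # stay unlinked distractors.
        n_extra = int(rng.poisson(cfg.entity_rate))
        for _ in range(n_extra):
            b.add_word(_pick(rng, _FILLER))
            if s not in link_sents and rng.random() < cfg.gene_disease_fraction:
                et = "Gene" if rng.random() < 0.5 else "Disease"
            else:
                pool = _OTHER_TYPES + _TRIGGER_TYPES if s not in link_sents else _OTHER_TYPES
                et = pool[int(rng.integers(len(pool)))]
            b.add_mention(_pick(rng, cfg.lexicon(et)), et)
        for _ in range(int(rng.integers(2, 5))):
            b.add_word(_pick(rng, _FILLER))
        b.words[-1] = b.words[-1] + "."
    return b.build(), gd_pairs


def generate_corpus(cfg: SynthConfig) -> list[AnnotatedDocument]:
    """Generate ``cfg.n_docs`` annotated documents; deterministic in (cfg, seed)."""
    return [_generate_doc(cfg, i)[0] for i in range(cfg.n_docs)]


def generate_corpus_with_links(
    cfg: SynthConfig,
) -> tuple[list[AnnotatedDocument], dict[str, list[tuple[str, str]]]]:
    """As :func:`generate_corpus`, plus the intended gene-disease pairs per doc.

    The bookkeeping lets tests check that direct-edge augmentation recovers
    exactly the pairs the generator meant to link.
    """
    docs, links = [], {}
    for i in range(cfg.n_docs):
        doc, pairs = _generate_doc(cfg, i)
        docs.append(doc)
        links[doc.doc_id] = pairs
    return docs, links


class CorruptionSpec(BaseModel):
    """Noise applied to gold relation sets to manufacture known P/R."""

    drop_rate: float = 0.0   # each gold edge dropped independently
    add_rate: float = 0.0    # expected spurious edges per document
    retype_rate: float = 0.0  # each surviving mention's type resampled


def generate_eval_pair(
    cfg: SynthConfig, corruption: CorruptionSpec
) -> tuple[list[AnnotatedDocument], list[AnnotatedDocument]]:
    """A gold corpus plus a corrupted copy acting as fake predictions.

    Against gold, the corrupted set has analytically known expected
    precision/recall: dropping edges at rate q gives recall ~ (1-q) with
    precision 1; adding spurious edges lowers precision and leaves recall 1.
    Used to validate the graph evaluator, not to train anything.
    """
    gold = generate_corpus(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2**20]))
    pred: list[AnnotatedDocument] = []
    for doc in gold:
        relations = [r for r in doc.relations if rng.random() >= corruption.drop_rate]
        mentions = list(doc.mentions)
        if corruption.retype_rate > 0:
            mentions = [
                m.model_copy(update={"etype": _pick(rng, list(ENTITY_TYPES))})
                if rng.random() < corruption.retype_rate
                else m
                for m in mentions
            ]
        n_add = int(rng.poisson(corruption.add_rate))
        existing = {frozenset((r.e0, r.e1)) for r in relations}
        ids = [m.id for m in doc.mentions]
        tries = 0
        while n_add > 0 and tries < 50 and len(ids) >= 2:
            u, v = rng.choice(len(ids), size=2, replace=False)
            key = frozenset((ids[u], ids[v]))
            gold_keys = {frozenset((r.e0, r.e1)) for r in doc.relations}
            tries += 1
            if key in existing or key in gold_keys:
                continue
            relations.append(RelationInstance(e0=ids[u], e1=ids[v], rtype=LINKED_OF))
            existing.add(key)
            n_add -= 1
        pred.append(
            AnnotatedDocument(
                doc_id=doc.doc_id, text=doc.text, mentions=mentions, relations=relations
            )
        )
    return gold, pred
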