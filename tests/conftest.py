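import numpy as np
import pytest

from gdlink.corpus_io import AnnotatedDocument, EntityMention, RelationInstance
from gdlink.model import JointExtractor
from gdlink.synth import SynthConfig, generate_corpus


def make_doc(doc_id: str, text: str, mentions, relations=()) -> AnnotatedDocument:
    """Build a document from (id, start, end, etype) tuples and (e0, e1[, direct])."""
    ms = [
        EntityMention(id=i, doc_id=doc_id, start=s, end=e, etype=t, surface=text[s:e])
        for (i, s, e, t) in mentions
    ]
    rs = [
        RelationInstance(e0=r[0], e1=r[1], direct=bool(r[2]) if len(r) > 2 else False)
        for r in relations
    ]
    return AnnotatedDocument(doc_id=doc_id, text=text, mentions=ms, relations=rs)


@pytest.fixture
def trigger_doc() -> AnnotatedDocument:
    """BRCA1 -> upregulates (PosReg trigger) -> melanoma."""
    text = "BRCA1 strongly upregulates cutaneous melanoma growth"
    return make_doc(
        "d1",
        text,
        [("g", 0, 5, "Gene"), ("t", 15, 26, "PosReg"), ("d", 37, 45, "Disease")],
        [("g", "t"), ("t", "d")],
    )


@pytest.fixture(scope="session")
def overfit_corpus() -> list[AnnotatedDocument]:
    return generate_corpus(SynthConfig(n_docs=20, seed=1))


@pytest.fixture(scope="session")
def overfit_joint(overfit_corpus) -> JointExtractor:
    """Joint model trained to saturation on 20 synthetic documents.

    The tiny encoder trains from random initialization, so the learning rate
    is larger than the fine-tuning default.
    """
    return JointExtractor(epochs=80, lr=3e-3, seed=1).fit(overfit_corpus)


@pytest.fixture(scope="session")
def overfit_onlyre(overfit_corpus) -> JointExtractor:
    """onlyRE model (gold entities, DE-augmented training) on the same corpus."""
    return JointExtractor(epochs=40, lr=1e-3, seed=1, only_re=True, de_augment=True).fit(
        overfit_corpus
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
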