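import numpy as np
import pytest

from meshrank import (
    Descriptor,
    Document,
    FixtureSpec,
    Vocabulary,
    make_corpus,
    make_vocabulary,
    preprocess,
)


@pytest.fixture
def toy_vocab() -> Vocabulary:
    """Five descriptors over the hierarchy A, A.1, A.1.1, B, B.1."""
    return Vocabulary(
        [
            Descriptor("DA", "alpha root", ["alfa"], ["A"]),
            Descriptor("DA1", "alpha mid", [], ["A.1"]),
            Descriptor("DA11", "alpha leaf", ["leafy alpha"], ["A.1.1"]),
            Descriptor("DB", "beta root", [], ["B"]),
            Descriptor("DB1", "beta leaf", [], ["B.1"]),
        ]
    )


@pytest.fixture
def small_docs() -> list[Document]:
    return [
        Document("d1", "alpha binding proteins", "study of alpha binding"),
        Document("d2", "beta signalling", "the beta pathway and binding"),
        Document("d3", "gamma unrelated", "completely different topic words"),
    ]


@pytest.fixture(scope="session")
def small_fixture():
    """Seeded 300-document synthetic corpus over the 39-label hierarchy."""
    spec = FixtureSpec(n_docs=300, seed=11)
    vocab, signatures = make_vocabulary(spec)
    docs = make_corpus(spec, vocab, signatures)
    return spec, vocab, signatures, docs


def processed(text: str, doc_id: str = "q"):
    return preprocess(Document(doc_id, text, ""))


def brute_force_ancestors(vocab: Vocabulary, descriptor_id: str) -> set[str]:
    """Oracle: materialize ancestors by repeated parent_map walks."""
    out: set[str] = set()
    for tn in vocab.get(descriptor_id).tree_numbers:
        cur = tn
        while cur in vocab.parent_map:
            cur = vocab.parent_map[cur]
            owner = vocab._tree_to_id.get(cur)
            if owner and owner != descriptor_id:
                out.add(owner)
    return out


def rng_for(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
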