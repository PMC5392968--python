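"""Synthetic vocabularies and corpora for end-to-end testing.

The generator builds a balanced toy hierarchy of descriptors, gives
each a small set of signature words, and writes documents whose text
mixes the signature words of their gold labels with background noise.
This realizes the statistical assumptions the method rests on:
documents sharing labels share vocabulary (so nearest neighbours carry
the right annotations), label text overlaps label names (so overlap,
translation and synonym features carry signal), and the number of
labels per document follows a skewed distribution with a realistic
mean (≈12.7 headings per article).  Age check tags are embedded as
explicit "aged N years" phrases consistent with the gold annotation.

Everything is seeded and reproducible; corpora round-trip through the
JSONL dialect.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
import os
from dataclasses import dataclass

import numpy as np

from .corpus import Document, ProcessedDoc
from .postprocess import DEFAULT_AGE_BRACKETS
from .text import DEFAULT_STOPWORDS, stem_tokens, tokenize
from .vocabulary import Descriptor, Vocabulary


@dataclass
class FixtureSpec:
    depth: int = 3
    branching: int = 3
    n_docs: int = 2000
    vocab_size: int = 2500  # total distinct word tokens (signatures + noise)
    words_per_label: int = 8
    labels_per_doc_mean: float = 12.7
    labels_per_doc_shape: float = 5.0  # negative-binomial dispersion
    noise_rate: float = 0.3
    check_tag_fraction: float = 0.25
    title_len: int = 8
    abstract_len: int = 80
    seed: int = 0

    def __post_init__(self):
        if min(self.depth, self.branching, self.n_docs, self.words_per_label) < 1:
            raise ValueError("all counts must be positive")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must be in [0, 1]")

    @property
    def n_labels(self) -> int:
        b = self.branching
        return sum(b**level for level in range(1, self.depth + 1))


_SYLLABLES = [
    "bak", "dun", "mol", "rit", "sev", "tor", "vel", "gam", "pix", "lod",
    "nar", "kuf", "zeb", "hin", "wop", "cyt", "fer", "gli", "hex", "jam",
]


def _make_word(rng: np.random.Generator, used: set[str]) -> str:
    """A stem-stable pseudoword (three CVC syllables, collision-free)."""
    from .text import porter_stem

    while True:
        w = "".join(rng.choice(_SYLLABLES, size=3))
        if w not in used and porter_stem(w) not in used:
            used.add(w)
            used.add(porter_stem(w))
            return w


def make_vocabulary(spec: FixtureSpec) -> tuple[Vocabulary, dict[str, list[str]]]:
    """Generate a toy vocabulary and its label → signature-word map.

    The hierarchy is a balanced forest (``branching`` roots, each node
    with ``branching`` children down to ``depth``).  A deterministic
    subset of the deepest descriptors is flagged as check tags; the
    first ten of those take the conventional age-group names so the
    age-tag rules resolve against the toy vocabulary.
    """
    rng = np.random.default_rng(spec.seed)
    used: set[str] = set()

    # tree numbers, breadth-first
    tree_numbers: list[str] = []
    frontier = [f"{i + 1:02d}" for i in range(spec.branching)]
    tree_numbers.extend(frontier)
    for _ in range(spec.depth - 1):
        nxt = []
        for tn in frontier:
            nxt.extend(f"{tn}.{k + 1}" for k in range(spec.branching))
        tree_numbers.extend(nxt)
        frontier = nxt

    n = len(tree_numbers)
    signatures: dict[str, list[str]] = {}
    descriptors: list[Descriptor] = []

    n_check = max(1, int(round(spec.check_tag_fraction * n)))
    check_positions = set(range(n - n_check, n))  # deepest descriptors
    age_names = [name for name, _, _ in DEFAULT_AGE_BRACKETS]
    age_assigned = 0

    for i, tn in enumerate(tree_numbers):
        did = f"D{i + 1:04d}"
        words = [_make_word(rng, used) for _ in range(spec.words_per_label)]
        signatures[did] = words
        is_check = i in check_positions
        if is_check and age_assigned < len(age_names):
            name = age_names[age_assigned]
            age_assigned += 1
        else:
            name = " ".join(words[:2])
        synonyms = []
        n_syn = int(rng.integers(0, 4))
        for s in range(n_syn):
            if s == 0 and rng.random() < 0.5 and len(words) > 2:
                synonyms.append(words[2])  # synonym drawn from the signature
            else:
                synonyms.append(_make_word(rng, used))
        descriptors.append(
            Descriptor(
                descriptor_id=did,
                preferred_name=name,
                synonyms=synonyms,
                tree_numbers=[tn],
                is_check_tag=is_check,
            )
        )
    return Vocabulary(descriptors), signatures


def _age_brackets_in(vocab: Vocabulary) -> dict[str, tuple[float, float]]:
    by_name = {d.preferred_name: d.descriptor_id for d in vocab.descriptors.values()}
    out = {}
    for name, lo, hi in DEFAULT_AGE_BRACKETS:
        if name in by_name:
            out[by_name[name]] = (lo, hi)
    return out


def make_corpus(
    spec: FixtureSpec,
    vocab: Vocabulary,
    signatures: dict[str, list[str]],
) -> list[Document]:
    """Generate documents with label-driven text.

    Label counts per document follow a truncated negative binomial
    with the configured mean; label identity follows a Zipf-like
    profile so frequency ranking is informative.  With noise_rate 0
    every content token comes from a gold label's signature.
    """
    rng = np.random.default_rng(spec.seed + 1)
    used = set()
    for words in signatures.values():
        used.update(words)
    n_noise = max(spec.vocab_size - len(used), 10)
    noise_pool = [_make_word(rng, used) for _ in range(n_noise)]

    label_ids = sorted(vocab.descriptors)
    weights = np.array([1.0 / (i + 1) ** 0.7 for i in range(len(label_ids))])
    weights /= weights.sum()

    age_brackets = _age_brackets_in(vocab)
    shape = spec.labels_per_doc_shape
    p_nb = shape / (shape + spec.labels_per_doc_mean)

    docs: list[Document] = []
    for d in range(spec.n_docs):
        n_lbl = int(rng.negative_binomial(shape, p_nb))
        n_lbl = min(max(n_lbl, 1), len(label_ids))
        gold = sorted(
            rng.choice(label_ids, size=n_lbl, replace=False, p=weights)
        )

        def draw_tokens(count: int) -> list[str]:
            out = []
            for _ in range(count):
                if noise_pool and rng.random() < spec.noise_rate:
                    out.append(noise_pool[int(rng.integers(0, len(noise_pool)))])
                else:
                    lbl = gold[int(rng.integers(0, len(gold)))]
                    words = signatures[lbl]
                    out.append(words[int(rng.integers(0, len(words)))])
            return out

        title = " ".join(draw_tokens(spec.title_len))
        abstract_words = draw_tokens(spec.abstract_len)
        # embed explicit age phrases consistent with gold age tags
        phrases = []
        for tag in gold:
            if tag in age_brackets:
                lo, hi = age_brackets[tag]
                hi_eff = hi if math.isfinite(hi) else lo + 240
                months = float(rng.uniform(lo, hi_eff))
                if hi_eff <= 24:
                    phrases.append(f"aged {max(int(months), 0)} months")
                else:
                    phrases.append(f"aged {int(months // 12)} years")
        abstract = " ".join(phrases + abstract_words)

        year = int(rng.integers(2008, 2015))
        month = int(rng.integers(1, 13))
        day = int(rng.integers(1, 29))
        docs.append(
            Document(
                doc_id=f"S{d + 1:06d}",
                title=title,
                abstract=abstract,
                gold_terms=list(gold),
                annotation_date=_dt.date(year, month, day),
            )
        )
    return docs


def pseudo_recommender(
    doc: Document | ProcessedDoc,
    vocab: Vocabulary,
    top_m: int = 10,
    stemmer: str = "porter",
) -> list[str]:
    """Rule-based external recommendation channel (name-overlap matcher).

    Ranks descriptors by the fraction of their preferred-name stemmed
    tokens present in the document and returns the top *m* with any
    overlap — a deliberately simple stand-in exercising the external
    recommender interface.
    """
    if isinstance(doc, ProcessedDoc):
        doc_tokens = set(doc.tokens)
    else:
        doc_tokens = set(
            stem_tokens(tokenize(doc.text), stemmer=stemmer,
                        stopwords=DEFAULT_STOPWORDS)
        )
    scored = []
    for did in sorted(vocab.descriptors):
        name_toks = stem_tokens(
            tokenize(vocab.descriptors[did].preferred_name),
            stemmer=stemmer,
            stopwords=DEFAULT_STOPWORDS,
        )
        if not name_toks:
            continue
        overlap = sum(t in doc_tokens for t in name_toks) / len(name_toks)
        if overlap > 0:
            scored.append((-overlap, did))
    scored.sort()
    return [did for _, did in scored[:top_m]]


def write_external_tsv(
    path: str | os.PathLike, recs: dict[str, list[str]]
) -> None:
    """External-recommender output dialect: doc_id TAB term,term,..."""
    with open(path, "w", encoding="utf-8") as fh:
        for did in sorted(recs):
            fh.write(f"{did}\t{','.join(recs[did])}\n")


def read_external_tsv(path: str | os.PathLike) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            did, _, terms = line.partition("\t")
            out[did] = [t for t in terms.split(",") if t]
    return out


def fixture_stats(docs: list[Document], vocab: Vocabulary) -> dict:
    counts = [len(d.gold_terms) for d in docs]
    return {
        "n_docs": len(docs),
        "n_labels": len(vocab),
        "mean_labels_per_doc": float(np.mean(counts)),
        "check_tags": sorted(vocab.check_tags()),
    }


def write_fixture(
    spec: FixtureSpec, out_dir: str | os.PathLike
) -> tuple[Vocabulary, list[Document]]:
    """Write vocabulary TSV + corpus JSONL + expected-stats JSON."""
    from .corpus import save_corpus_jsonl
    from .vocabulary import save_vocabulary_tsv

    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    vocab, signatures = make_vocabulary(spec)
    docs = make_corpus(spec, vocab, signatures)
    save_vocabulary_tsv(vocab, os.path.join(out_dir, "vocabulary.tsv"))
    save_corpus_jsonl(docs, os.path.join(out_dir, "corpus.jsonl"))
    with open(os.path.join(out_dir, "expected_stats.json"), "w") as fh:
        json.dump(fixture_stats(docs, vocab), fh, indent=1)
    return vocab, docs
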