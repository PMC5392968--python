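"""Candidate-term assembly and ranking-feature extraction.

Candidates for a document come from three sources — labels harvested
from nearest-neighbour annotations, positively classified labels, and
an external recommender — merged into one deduplicated list with
provenance flags.  Each candidate then gets a fixed-schema feature
vector combining neighbourhood evidence, lexical overlap with the term
name, translation and query-likelihood scores, synonym mentions, the
classifier decision value, and the external-recommender flag.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np

from .classification import LabelModelBattery, predict_score
from .corpus import Neighbour, ProcessedDoc
from .retrieval import (
    BackgroundStats,
    TranslationTable,
    bm25_score,
    translation_query_likelihood,
)
from .text import DEFAULT_STOPWORDS, stem_tokens, tokenize
from .vocabulary import Vocabulary

#: Fixed feature schema: order is part of any trained ranker's contract.
FEATURE_NAMES: tuple[str, ...] = (
    "nbr_freq",
    "nbr_sim_sum",
    "unigram_overlap",
    "bigram_overlap",
    "translation_prob",
    "bm25",
    "trans_query_ll",
    "synonym_match",
    "classifier_score",
    "classifier_present",
    "external_flag",
)

#: Floor for per-token translation maxima (keeps the product positive).
TRANSLATION_FLOOR = 1e-9

#: Finite stand-in for −inf query log-likelihoods in feature vectors.
_LL_FLOOR = -1e6


def feature_schema_hash(names: tuple[str, ...] = FEATURE_NAMES) -> str:
    return hashlib.sha256("\x1f".join(names).encode()).hexdigest()[:16]


@dataclass
class CandidateTerm:
    descriptor_id: str
    from_knn: bool = False
    from_classifier: bool = False
    from_external: bool = False
    classifier_score: float | None = None

    def __post_init__(self):
        if not (self.from_knn or self.from_classifier or self.from_external):
            raise ValueError(
                f"candidate {self.descriptor_id!r} has no source flag set"
            )


def generate_candidates(
    doc: ProcessedDoc,
    neighbours: list[Neighbour],
    neighbour_annotations: dict[str, list[str]],
    models: LabelModelBattery | None = None,
    external: list[str] | None = None,
) -> list[CandidateTerm]:
    """Merge the three candidate sources for one document.

    Source flags are OR-ed on duplicates; the classifier decision value
    is attached to every candidate whose label has a trained model,
    whether or not the classifier itself proposed it.  Returned in
    deterministic (sorted-id) order.
    """
    flags: dict[str, dict[str, bool]] = {}

    def entry(did: str) -> dict[str, bool]:
        return flags.setdefault(
            did, {"knn": False, "clf": False, "ext": False}
        )

    for nb in neighbours:
        for did in neighbour_annotations.get(nb.doc_id, []):
            entry(did)["knn"] = True
    scores: dict[str, float] = {}
    if models is not None:
        scores = models.scores(doc)
        for did, s in scores.items():
            if s > 0:
                entry(did)["clf"] = True
    if external:
        for did in external:
            entry(did)["ext"] = True

    out = [
        CandidateTerm(
            descriptor_id=did,
            from_knn=f["knn"],
            from_classifier=f["clf"],
            from_external=f["ext"],
            classifier_score=scores.get(did),
        )
        for did, f in sorted(flags.items())
    ]
    if not out:
        warnings.warn(f"no candidate terms generated for {doc.doc_id!r}",
                      stacklevel=2)
    return out


def _name_tokens(
    name: str, stemmer: str, stopwords: frozenset[str]
) -> list[str]:
    return stem_tokens(tokenize(name), stemmer=stemmer, stopwords=stopwords)


def _bigrams(tokens: list[str]) -> set[tuple[str, str]]:
    return set(zip(tokens, tokens[1:]))


def extract_features(
    doc: ProcessedDoc,
    cand: CandidateTerm,
    vocab: Vocabulary,
    neighbours: list[Neighbour],
    neighbour_annotations: dict[str, list[str]],
    tt: TranslationTable | None,
    bg: BackgroundStats,
    stemmer: str = "porter",
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
) -> np.ndarray:
    """Feature vector for one candidate, in :data:`FEATURE_NAMES` order.

    Overlap features use the stemmed tokens of the preferred name only;
    synonyms feed the binary synonym feature (case-folded substring
    match against title + abstract).  The translation feature is the
    product over name tokens of the best per-document-token
    translation probability, floored so absent evidence stays
    distinguishable from zero-length names.
    """
    desc = vocab.get(cand.descriptor_id)
    name_toks = _name_tokens(desc.preferred_name, stemmer, stopwords)

    nbr_with = [
        nb
        for nb in neighbours
        if cand.descriptor_id in neighbour_annotations.get(nb.doc_id, [])
    ]
    nbr_freq = float(len(nbr_with))
    nbr_sim_sum = float(sum(nb.similarity for nb in nbr_with))

    doc_token_set = set(doc.tokens)
    if name_toks:
        unigram_overlap = sum(t in doc_token_set for t in name_toks) / len(name_toks)
    else:
        unigram_overlap = 0.0
    name_bg = _bigrams(name_toks)
    if name_bg:
        doc_bg = _bigrams(doc.tokens)
        bigram_overlap = len(name_bg & doc_bg) / len(name_bg)
    else:
        bigram_overlap = 0.0

    if tt is not None and name_toks:
        prod = 1.0
        for q in name_toks:
            best = max(
                (tt.prob(q, w) for w in doc.tf), default=0.0
            )
            prod *= max(best, TRANSLATION_FLOOR)
        translation_prob = prod
    else:
        translation_prob = 0.0

    bm25 = bm25_score(name_toks, doc, bg) if name_toks else 0.0
    if tt is not None and name_toks:
        ll = translation_query_likelihood(name_toks, doc, tt, bg)
        trans_query_ll = ll if np.isfinite(ll) else _LL_FLOOR
    else:
        trans_query_ll = _LL_FLOOR

    raw_text = f"{doc.title} {doc.abstract}".lower()
    synonym_match = float(
        any(s.lower() in raw_text for s in desc.synonyms if s)
    )

    classifier_present = float(cand.classifier_score is not None)
    classifier_score = cand.classifier_score or 0.0

    return np.array(
        [
            nbr_freq,
            nbr_sim_sum,
            unigram_overlap,
            bigram_overlap,
            translation_prob,
            bm25,
            trans_query_ll,
            synonym_match,
            classifier_score,
            classifier_present,
            float(cand.from_external),
        ],
        dtype=np.float64,
    )


def features_for_candidates(
    doc: ProcessedDoc,
    candidates: list[CandidateTerm],
    vocab: Vocabulary,
    neighbours: list[Neighbour],
    neighbour_annotations: dict[str, list[str]],
    tt: TranslationTable | None,
    bg: BackgroundStats,
    **kw,
) -> np.ndarray:
    """Stack feature vectors for a whole candidate list (n × d)."""
    if not candidates:
        return np.zeros((0, len(FEATURE_NAMES)))
    return np.vstack(
        [
            extract_features(
                doc, c, vocab, neighbours, neighbour_annotations, tt, bg, **kw
            )
            for c in candidates
        ]
    )


def write_candidate_tsv(path, rows) -> None:
    """Ranker training exchange format.

    *rows* yields (doc_id, descriptor_id, label, feature_vector).
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("doc_id\tdescriptor_id\tlabel\t" + "\t".join(FEATURE_NAMES) + "\n")
        for doc_id, did, label, feats in rows:
            vals = "\t".join(f"{v:.10g}" for v in feats)
            fh.write(f"{doc_id}\t{did}\t{int(label)}\t{vals}\n")


def read_candidate_tsv(path):
    """Yield (doc_id, descriptor_id, label, feature array) records."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["doc_id", "descriptor_id", "label", *FEATURE_NAMES]
        if header != expected:
            raise ValueError(f"{path}: unexpected candidate TSV header")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            yield (
                parts[0],
                parts[1],
                int(parts[2]),
                np.array([float(v) for v in parts[3:]]),
            )
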