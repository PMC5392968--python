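"""Retrieval models feeding the ranking features.

Three scoring families treat a candidate term's name as a query
against the document text:

* IBM Model 1 translation probabilities t(term_token | doc_token),
  trained by EM on (term tokens, document tokens) pairs with the
  document side as the conditioning (source) language;
* Okapi BM25 with the conventional saturation/length normalization;
* a translation-based query likelihood mixing document translation
  evidence with a background unigram model (Jelinek-Mercer).

Background statistics (document frequencies, average length) come from
a sample of the training corpus.
"""

from __future__ import annotations

import gzip
import json
import math
import os
from dataclasses import dataclass, field

from .corpus import ProcessedDoc

NEG_INF = float("-inf")


@dataclass
class BackgroundStats:
    """Collection statistics for the retrieval models."""

    doc_freq: dict[str, int]
    n_docs: int
    avg_doc_len: float
    total_df: int = field(init=False)

    def __post_init__(self):
        for t, df in self.doc_freq.items():
            if not 0 < df <= self.n_docs:
                raise ValueError(f"doc_freq[{t!r}]={df} outside (0, n_docs]")
        self.total_df = sum(self.doc_freq.values())

    def p_background(self, token: str) -> float:
        """Smoothed background unigram probability (strictly positive)."""
        df = self.doc_freq.get(token, 0)
        return (df + 0.5) / (self.total_df + 0.5 * (len(self.doc_freq) + 1))

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "doc_freq": self.doc_freq,
                    "n_docs": self.n_docs,
                    "avg_doc_len": self.avg_doc_len,
                },
                fh,
            )

    @staticmethod
    def load(path: str | os.PathLike) -> "BackgroundStats":
        with open(path) as fh:
            d = json.load(fh)
        return BackgroundStats(
            doc_freq=d["doc_freq"],
            n_docs=d["n_docs"],
            avg_doc_len=d["avg_doc_len"],
        )


def background_stats_from_docs(docs: list[ProcessedDoc]) -> BackgroundStats:
    if not docs:
        raise ValueError("cannot compute background stats from an empty sample")
    df: dict[str, int] = {}
    for d in docs:
        for t in d.tf:
            df[t] = df.get(t, 0) + 1
    avg = sum(d.length for d in docs) / len(docs)
    return BackgroundStats(doc_freq=df, n_docs=len(docs), avg_doc_len=avg)


# ---------------------------------------------------------------------------
# IBM Model 1
# ---------------------------------------------------------------------------

class TranslationTable:
    """t(term_token | doc_token) translation probabilities.

    For every conditioning doc_token the probabilities over term tokens
    sum to one (checked after each EM iteration).
    """

    def __init__(self, t: dict[str, dict[str, float]]):
        self.t = t  # doc_token -> {term_token: prob}
        self.source_vocab = sorted(t)
        target: set[str] = set()
        for probs in t.values():
            target.update(probs)
        self.target_vocab = sorted(target)

    def prob(self, term_token: str, doc_token: str) -> float:
        return self.t.get(doc_token, {}).get(term_token, 0.0)

    def check_normalized(self, tol: float = 1e-9) -> None:
        for w, probs in self.t.items():
            s = sum(probs.values())
            if abs(s - 1.0) > tol:
                raise AssertionError(
                    f"translation probabilities for {w!r} sum to {s}, not 1"
                )

    def save(self, path: str | os.PathLike) -> None:
        """Persist as gzip TSV: term_token, doc_token, probability."""
        with gzip.open(path, "wt", encoding="utf-8") as fh:
            for w in sorted(self.t):
                for q in sorted(self.t[w]):
                    fh.write(f"{q}\t{w}\t{self.t[w][q]:.12g}\n")

    @staticmethod
    def load(path: str | os.PathLike) -> "TranslationTable":
        t: dict[str, dict[str, float]] = {}
        with gzip.open(path, "rt", encoding="utf-8") as fh:
            for line in fh:
                q, w, p = line.rstrip("\n").split("\t")
                t.setdefault(w, {})[q] = float(p)
        return TranslationTable(t)


def ibm1_log_likelihood(
    pairs: list[tuple[list[str], list[str]]], tt: TranslationTable
) -> float:
    """Model-1 data log-likelihood (uniform alignment prior, no NULL)."""
    ll = 0.0
    for term_toks, doc_toks in pairs:
        if not doc_toks:
            continue
        for q in term_toks:
            p = sum(tt.prob(q, w) for w in doc_toks) / len(doc_toks)
            ll += math.log(p) if p > 0 else -1e300
    return ll


def train_ibm1(
    pairs: list[tuple[list[str], list[str]]],
    iters: int = 20,
    seed: int = 0,
    tol: float = 1e-4,
) -> TranslationTable:
    """EM for IBM Model 1 from a uniform start.

    *pairs* are (term tokens, document tokens); the trained direction
    is t(term_token | doc_token).  Stops after *iters* iterations or
    when the log-likelihood improves by less than *tol*.  Model 1's EM
    objective is concave, so the uniform start is also the canonical
    one; *seed* is accepted for interface uniformity but unused.
    """
    del seed
    pairs = [(tq, tw) for tq, tw in pairs if tq and tw]
    if not pairs:
        raise ValueError("no non-empty training pairs")

    target_vocab: set[str] = set()
    for tq, _ in pairs:
        target_vocab.update(tq)
    uniform = 1.0 / len(target_vocab)
    t: dict[str, dict[str, float]] = {}
    for tq, tw in pairs:
        for w in tw:
            probs = t.setdefault(w, {})
            for q in tq:
                probs.setdefault(q, uniform)
    # renormalize the uniform start over each doc_token's reachable terms
    for w, probs in t.items():
        z = sum(probs.values())
        for q in probs:
            probs[q] /= z

    table = TranslationTable(t)
    prev_ll = ibm1_log_likelihood(pairs, table)
    for _ in range(iters):
        counts: dict[str, dict[str, float]] = {w: {} for w in t}
        totals: dict[str, float] = {w: 0.0 for w in t}
        for tq, tw in pairs:
            for q in tq:
                denom = sum(t[w].get(q, 0.0) for w in tw)
                if denom <= 0:
                    continue
                for w in tw:
                    frac = t[w].get(q, 0.0) / denom
                    if frac:
                        counts[w][q] = counts[w].get(q, 0.0) + frac
                        totals[w] += frac
        for w in t:
            if totals[w] > 0:
                t[w] = {q: c / totals[w] for q, c in counts[w].items()}
        table = TranslationTable(t)
        table.check_normalized()
        ll = ibm1_log_likelihood(pairs, table)
        if ll - prev_ll < tol:
            prev_ll = ll
            break
        prev_ll = ll
    return table


# ---------------------------------------------------------------------------
# BM25 and translation query likelihood
# ---------------------------------------------------------------------------

def bm25_score(
    query_tokens: list[str],
    doc: ProcessedDoc,
    bg: BackgroundStats,
    k1: float = 1.2,
    b: float = 0.75,
) -> float:
    """Okapi BM25 of the query against one document.

    idf(q) = ln((n − df + 0.5)/(df + 0.5) + 1); unseen query tokens
    take df = 0 and simply contribute through that branch (zero when
    absent from the document).
    """
    n = bg.n_docs
    score = 0.0
    for q in query_tokens:
        tf = doc.tf.get(q, 0)
        if tf == 0:
            continue
        df = bg.doc_freq.get(q, 0)
        idf = math.log((n - df + 0.5) / (df + 0.5) + 1.0)
        denom = tf + k1 * (1.0 - b + b * doc.length / bg.avg_doc_len)
        score += idf * tf * (k1 + 1.0) / denom
    return score


def translation_query_likelihood(
    query_tokens: list[str],
    doc: ProcessedDoc,
    tt: TranslationTable,
    bg: BackgroundStats,
    mix: float = 0.5,
) -> float:
    """Log-likelihood of the query under a translation document model.

    For each query token q:
        log( mix · Σ_w t(q|w) · p_ml(w|doc) + (1 − mix) · p_bg(q) )
    with p_ml the maximum-likelihood document unigram model.  With
    mix = 1 and no translation evidence the result is −inf (sentinel).
    """
    if not 0.0 <= mix <= 1.0:
        raise ValueError("mix must be in [0, 1]")
    total = 0.0
    length = doc.length or 1
    for q in query_tokens:
        trans = sum(
            tt.prob(q, w) * (c / length) for w, c in doc.tf.items()
        )
        p = mix * trans + (1.0 - mix) * bg.p_background(q)
        if p <= 0.0:
            return NEG_INF
        total += math.log(p)
    return total
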