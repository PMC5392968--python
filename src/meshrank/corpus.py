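"""Document corpus handling and k-nearest-neighbour retrieval.

Documents (title + abstract, with gold annotations when available) are
preprocessed into stemmed, stop-word-free token streams and indexed in
a tf-idf vector space.  Neighbour retrieval supports a dynamic *k*:
the better the candidate neighbours match on average, the more of them
are used, linearly between ``k_min`` and ``k_max``.  Gold annotations
never contribute to similarity — only running text is indexed — and
the index can be restricted to recently annotated documents, since
older records carry annotations made against older vocabulary
editions.
"""

from __future__ import annotations

import datetime as _dt
import json
import os
import pickle
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from lxml import etree

from .text import DEFAULT_STOPWORDS, stem_tokens, tokenize

_INDEX_SCHEMA_VERSION = 1


@dataclass
class Document:
    doc_id: str
    title: str
    abstract: str
    gold_terms: list[str] = field(default_factory=list)
    annotation_date: _dt.date | None = None

    def __post_init__(self):
        if not self.title and not self.abstract:
            raise ValueError(f"document {self.doc_id!r}: title and abstract both empty")

    @property
    def text(self) -> str:
        return f"{self.title} {self.abstract}".strip()


@dataclass
class ProcessedDoc:
    """Tokenized, stemmed document with a term-frequency vector."""

    doc_id: str
    tokens: list[str]
    tf: dict[str, int]
    length: int
    title: str = ""
    abstract: str = ""


@dataclass
class KnnConfig:
    """Dynamic-k neighbour retrieval parameters.

    ``probe`` candidates are fetched; their mean similarity s̄ is mapped
    linearly onto [k_min, k_max] between the ``sim_low`` / ``sim_high``
    thresholds (clamped outside).
    """

    k_min: int = 10
    k_max: int = 40
    probe: int | None = None  # defaults to k_max
    sim_low: float | None = None  # defaults from index percentiles
    sim_high: float | None = None

    def __post_init__(self):
        if self.k_min > self.k_max:
            raise ValueError("k_min must be <= k_max")
        if (
            self.sim_low is not None
            and self.sim_high is not None
            and not self.sim_low < self.sim_high
        ):
            raise ValueError("sim_low must be < sim_high")


@dataclass
class Neighbour:
    doc_id: str
    similarity: float


class NeighbourList(list):
    """List of :class:`Neighbour` with an underfill warning flag."""

    underfilled: bool = False


def preprocess(
    d: Document,
    stemmer: str = "porter",
    stopwords: frozenset[str] | set[str] = DEFAULT_STOPWORDS,
) -> ProcessedDoc:
    """Case-fold, tokenize, drop stop words and stem a document."""
    tokens = stem_tokens(tokenize(d.text), stemmer=stemmer, stopwords=stopwords)
    tf: dict[str, int] = {}
    for t in tokens:
        tf[t] = tf.get(t, 0) + 1
    return ProcessedDoc(
        doc_id=d.doc_id,
        tokens=tokens,
        tf=tf,
        length=len(tokens),
        title=d.title,
        abstract=d.abstract,
    )


class SimilarityIndex:
    """tf-idf cosine index over preprocessed documents.

    idf(t) = ln((N+1)/(df(t)+1)) + 1 (smoothed, strictly positive); row
    vectors are L2-normalized so document-document similarity is the
    sparse dot product.  The index also keeps the document frequencies
    and average length needed by the retrieval feature models.
    """

    def __init__(
        self,
        processed: list[ProcessedDoc],
        annotations: dict[str, list[str]],
        stemmer: str = "porter",
        stopwords: frozenset[str] | set[str] = DEFAULT_STOPWORDS,
    ):
        if not processed:
            raise ValueError("cannot build an index over an empty corpus")
        self.docs: dict[str, ProcessedDoc] = {p.doc_id: p for p in processed}
        self.doc_ids: list[str] = [p.doc_id for p in processed]
        self.annotations = annotations
        self.stemmer = stemmer
        self.stopwords = frozenset(stopwords)

        vocab: dict[str, int] = {}
        for p in processed:
            for t in p.tf:
                if t not in vocab:
                    vocab[t] = len(vocab)
        self.vocab = vocab

        n, m = len(processed), max(len(vocab), 1)
        self.n_docs = n
        self.avg_doc_len = float(np.mean([p.length for p in processed]))
        df = np.zeros(m, dtype=np.int64)
        rows, cols, vals = [], [], []
        for i, p in enumerate(processed):
            for t, c in p.tf.items():
                j = vocab[t]
                rows.append(i)
                cols.append(j)
                vals.append(c)
                df[j] += 1
        self.df = df
        self.idf = np.log((n + 1) / (df + 1.0)) + 1.0
        mat = sp.csr_matrix(
            (np.asarray(vals, dtype=np.float64), (rows, cols)), shape=(n, m)
        )
        mat = mat.multiply(self.idf[None, :]).tocsr()
        norms = np.sqrt(np.asarray(mat.multiply(mat).sum(axis=1)).ravel())
        norms[norms == 0] = 1.0
        self.matrix = sp.diags(1.0 / norms) @ mat
        self.sim_low, self.sim_high = self._calibrate_dynamic_k()

    # -- vectorization ----------------------------------------------------

    def doc_freq(self, token: str) -> int:
        j = self.vocab.get(token)
        return int(self.df[j]) if j is not None else 0

    def vectorize(self, p: ProcessedDoc) -> sp.csr_matrix:
        """tf-idf vector of *p* in the index space, L2-normalized.

        Tokens unseen at build time are ignored (they cannot match any
        indexed document).
        """
        cols, vals = [], []
        for t, c in p.tf.items():
            j = self.vocab.get(t)
            if j is not None:
                cols.append(j)
                vals.append(c * self.idf[j])
        v = sp.csr_matrix(
            (vals, ([0] * len(cols), cols)), shape=(1, self.matrix.shape[1])
        )
        norm = np.sqrt(v.multiply(v).sum())
        if norm > 0:
            v = v / norm
        return v

    def _calibrate_dynamic_k(self, probe: int = 40, max_sample: int = 500):
        """Default sim_low/sim_high: 10th/90th percentile of per-document
        neighbour-mean similarity, on a deterministic stride subsample."""
        n = self.n_docs
        stride = max(1, -(-n // max_sample))
        sample = list(range(0, n, stride))
        means = []
        sub = self.matrix[sample]
        sims_all = (sub @ self.matrix.T).toarray()
        for row_pos, i in enumerate(sample):
            sims = sims_all[row_pos]
            sims[i] = -np.inf  # exclude self
            top = np.sort(sims)[::-1][: min(probe, n - 1)]
            top = top[np.isfinite(top)]
            if top.size:
                means.append(float(np.mean(np.maximum(top, 0.0))))
        if not means:
            return 0.0, 1.0
        lo = float(np.percentile(means, 10))
        hi = float(np.percentile(means, 90))
        if not lo < hi:  # degenerate (tiny or uniform corpora)
            lo, hi = max(lo - 0.05, 0.0), lo + 0.05
        return lo, hi

    # -- persistence ------------------------------------------------------

    def save(self, path: str | os.PathLike) -> None:
        payload = {
            "schema_version": _INDEX_SCHEMA_VERSION,
            "index": self,
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @staticmethod
    def load(path: str | os.PathLike) -> "SimilarityIndex":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("schema_version") != _INDEX_SCHEMA_VERSION:
            raise ValueError(
                f"{path}: index schema version "
                f"{payload.get('schema_version')!r} not supported"
            )
        return payload["index"]


def build_index(
    corpus: list[Document],
    date_floor: _dt.date | None = None,
    exclude_terms: bool = True,
    stemmer: str = "porter",
    stopwords: frozenset[str] | set[str] = DEFAULT_STOPWORDS,
) -> SimilarityIndex:
    """Index *corpus*, optionally restricted to recent annotations.

    Documents with ``annotation_date`` before *date_floor* (or with no
    date, when a floor is given) are dropped.  Gold annotations are
    stored for candidate harvesting; with ``exclude_terms`` (the
    default, matching indexing practice) they never contribute tokens
    to the similarity space — only running text does.  Setting it
    False appends the annotation ids as opaque pseudo-tokens, which is
    occasionally useful for diagnostics.
    """
    kept = [
        d
        for d in corpus
        if date_floor is None
        or (d.annotation_date is not None and d.annotation_date >= date_floor)
    ]
    if not kept:
        raise ValueError("no documents remain after date filtering")
    processed = []
    for d in kept:
        p = preprocess(d, stemmer=stemmer, stopwords=stopwords)
        if not exclude_terms:
            for term in d.gold_terms:
                tok = term.lower()
                p.tokens.append(tok)
                p.tf[tok] = p.tf.get(tok, 0) + 1
            p.length = len(p.tokens)
        processed.append(p)
    annotations = {d.doc_id: list(d.gold_terms) for d in kept}
    return SimilarityIndex(processed, annotations, stemmer=stemmer,
                           stopwords=stopwords)


def similarity(index: SimilarityIndex, a: ProcessedDoc, b: ProcessedDoc) -> float:
    """tf-idf cosine similarity between two preprocessed documents."""
    va = index.vectorize(a)
    vb = index.vectorize(b)
    return float((va @ vb.T).toarray()[0, 0])


def knn_retrieve(
    index: SimilarityIndex, q: ProcessedDoc, cfg: KnnConfig | None = None
) -> NeighbourList:
    """Retrieve the dynamically-sized nearest-neighbour list of *q*.

    The top ``probe`` candidates (by similarity, self excluded) set the
    mean similarity s̄; k = round(k_min + (k_max − k_min) ·
    clamp((s̄ − sim_low)/(sim_high − sim_low), 0, 1)).  Ties are broken
    by doc_id so results are total-ordered.
    """
    cfg = cfg or KnnConfig()
    probe = cfg.probe if cfg.probe is not None else cfg.k_max
    sim_low = cfg.sim_low if cfg.sim_low is not None else index.sim_low
    sim_high = cfg.sim_high if cfg.sim_high is not None else index.sim_high

    v = index.vectorize(q)
    sims = (index.matrix @ v.T).toarray().ravel()
    order = sorted(
        range(index.n_docs),
        key=lambda i: (-sims[i], index.doc_ids[i]),
    )
    order = [i for i in order if index.doc_ids[i] != q.doc_id]

    top = order[:probe]
    result = NeighbourList()
    if not top:
        result.underfilled = True
        return result
    s_bar = float(np.mean([sims[i] for i in top]))
    span = sim_high - sim_low
    frac = min(max((s_bar - sim_low) / span, 0.0), 1.0) if span > 0 else 0.0
    k = int(np.floor(cfg.k_min + (cfg.k_max - cfg.k_min) * frac + 0.5))

    chosen = order[:k]
    if len(chosen) < cfg.k_min:
        result.underfilled = True
        warnings.warn(
            f"only {len(chosen)} neighbour candidates available for "
            f"{q.doc_id!r} (k_min={cfg.k_min})",
            stacklevel=2,
        )
    result.extend(
        Neighbour(doc_id=index.doc_ids[i], similarity=float(sims[i])) for i in chosen
    )
    return result


# ---------------------------------------------------------------------------
# Corpus I/O: JSONL and MEDLINE-style XML
# ---------------------------------------------------------------------------

def _parse_date(s: str | None) -> _dt.date | None:
    return _dt.date.fromisoformat(s) if s else None


def load_corpus_jsonl(path: str | os.PathLike) -> list[Document]:
    docs = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: bad JSON: {exc}") from exc
            did = str(rec["doc_id"])
            if did in seen:
                raise ValueError(f"{path}:{lineno}: duplicate doc_id {did!r}")
            seen.add(did)
            docs.append(
                Document(
                    doc_id=did,
                    title=rec.get("title", ""),
                    abstract=rec.get("abstract", ""),
                    gold_terms=list(rec.get("gold_terms", [])),
                    annotation_date=_parse_date(rec.get("annotation_date")),
                )
            )
    return docs


def save_corpus_jsonl(docs: list[Document], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            rec = {
                "doc_id": d.doc_id,
                "title": d.title,
                "abstract": d.abstract,
                "gold_terms": d.gold_terms,
                "annotation_date": (
                    d.annotation_date.isoformat() if d.annotation_date else None
                ),
            }
            fh.write(json.dumps(rec) + "\n")


def load_corpus_medline_xml(path: str | os.PathLike) -> list[Document]:
    """Read a MEDLINE-style citation XML file.

    Recognized elements per article: PMID, ArticleTitle, AbstractText,
    MeshHeadingList/MeshHeading/DescriptorName[@UI], DateCompleted.
    """
    try:
        tree = etree.parse(os.fspath(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"{path}: malformed XML: {exc}") from exc
    docs = []
    seen: set[str] = set()
    for cit in tree.iter("MedlineCitation"):
        pmid = cit.findtext("PMID")
        if not pmid:
            raise ValueError(
                f"{path}: MedlineCitation at line {cit.sourceline} lacks PMID"
            )
        if pmid in seen:
            raise ValueError(f"{path}: duplicate PMID {pmid!r}")
        seen.add(pmid)
        title = cit.findtext("Article/ArticleTitle") or ""
        abstract = " ".join(
            t.text for t in cit.findall("Article/Abstract/AbstractText") if t.text
        )
        terms = []
        for mh in cit.findall("MeshHeadingList/MeshHeading/DescriptorName"):
            ui = mh.get("UI") or mh.text
            if ui and ui not in terms:
                terms.append(ui)
        date = None
        dc = cit.find("DateCompleted")
        if dc is not None:
            try:
                date = _dt.date(
                    int(dc.findtext("Year")),
                    int(dc.findtext("Month")),
                    int(dc.findtext("Day")),
                )
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path}: bad DateCompleted at line {dc.sourceline}: {exc}"
                ) from exc
        docs.append(
            Document(
                doc_id=pmid,
                title=title,
                abstract=abstract,
                gold_terms=terms,
                annotation_date=date,
            )
        )
    return docs


def save_corpus_medline_xml(docs: list[Document], path: str | os.PathLike) -> None:
    root = etree.Element("PubmedArticleSet")
    for d in docs:
        art = etree.SubElement(root, "PubmedArticle")
        cit = etree.SubElement(art, "MedlineCitation")
        etree.SubElement(cit, "PMID").text = d.doc_id
        if d.annotation_date:
            dc = etree.SubElement(cit, "DateCompleted")
            etree.SubElement(dc, "Year").text = str(d.annotation_date.year)
            etree.SubElement(dc, "Month").text = str(d.annotation_date.month)
            etree.SubElement(dc, "Day").text = str(d.annotation_date.day)
        article = etree.SubElement(cit, "Article")
        etree.SubElement(article, "ArticleTitle").text = d.title
        if d.abstract:
            ab = etree.SubElement(article, "Abstract")
            etree.SubElement(ab, "AbstractText").text = d.abstract
        if d.gold_terms:
            mhl = etree.SubElement(cit, "MeshHeadingList")
            for t in d.gold_terms:
                mh = etree.SubElement(mhl, "MeshHeading")
                dn = etree.SubElement(mh, "DescriptorName")
                dn.set("UI", t)
                dn.text = t
    etree.ElementTree(root).write(
        os.fspath(path), pretty_print=True, xml_declaration=True, encoding="utf-8"
    )


def load_corpus(path: str | os.PathLike, dialect: str | None = None) -> list[Document]:
    """Load a corpus, inferring the dialect from the extension if unset."""
    p = os.fspath(path)
    if dialect is None:
        dialect = "medline-xml" if p.endswith(".xml") else "jsonl"
    if dialect == "jsonl":
        return load_corpus_jsonl(p)
    if dialect == "medline-xml":
        return load_corpus_medline_xml(p)
    raise ValueError(f"unknown corpus dialect {dialect!r}")
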