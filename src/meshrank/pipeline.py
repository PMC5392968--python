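"""End-to-end orchestration: train, predict, evaluate.

``train`` builds every artifact the predictor needs — the similarity
index, the per-label classifier battery, the translation table and
background statistics, and the trained ranker — under one artifact
directory.  ``predict`` scores documents into ranked, pruned term
lists; ``evaluate`` compares predictions against gold annotations.
All randomness (ranker-document sampling, negative subsampling, SGD
order) flows from the single configured seed, and per-document /
per-label work is order-independent so results do not depend on
worker counts.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed

from .classification import LabelModelBattery, SvmConfig, train_all
from .corpus import (
    Document,
    KnnConfig,
    SimilarityIndex,
    build_index,
    knn_retrieve,
    load_corpus,
    preprocess,
)
from .evaluate import EvalReport, evaluate_corpus
from .features import (
    FEATURE_NAMES,
    features_for_candidates,
    generate_candidates,
    write_candidate_tsv,
)
from .postprocess import PruningConfig, default_age_rules, postprocess
from .ranker import (
    LambdaMartConfig,
    LambdaMARTModel,
    PredictionList,
    ScoredTerm,
    score_candidates,
    train_lambdamart,
)
from .retrieval import (
    BackgroundStats,
    TranslationTable,
    background_stats_from_docs,
    train_ibm1,
)
from .synthetic import pseudo_recommender, read_external_tsv
from .text import DEFAULT_STOPWORDS, stem_tokens, tokenize
from .vocabulary import Vocabulary, load_vocabulary

logger = logging.getLogger("meshrank")

_ARTIFACTS = {
    "index": "index.bin",
    "classifiers": "classifiers",
    "translation": "translation.tsv.gz",
    "background": "background.json",
    "ranker": "ranker.json",
}


@dataclass
class PipelineConfig:
    """One config object for the whole pipeline (JSON/TOML-loadable)."""

    seed: int = 0
    stemmer: str = "porter"
    date_floor: str | None = "2009-01-01"
    # neighbour retrieval
    k_min: int = 10
    k_max: int = 40
    # classifier battery
    n_classifier_labels: int = 20000
    svm: SvmConfig = field(default_factory=SvmConfig)
    # translation / background models
    translation_pairs: int = 2000
    translation_doc_tokens: int = 60
    translation_iters: int = 20
    background_sample: int = 60000
    # ranker
    ranker_train_docs: int = 5000
    ranker: LambdaMartConfig = field(default_factory=LambdaMartConfig)
    # pruning
    pruning: PruningConfig = field(default_factory=PruningConfig)
    use_pseudo_external: bool = False
    external_top_m: int = 10
    n_jobs: int = 1

    def __post_init__(self):
        # propagate the top-level seed to sub-configs left at default
        self.svm.seed = self.seed
        self.ranker.seed = self.seed

    @property
    def date_floor_date(self) -> _dt.date | None:
        return _dt.date.fromisoformat(self.date_floor) if self.date_floor else None

    @property
    def knn(self) -> KnnConfig:
        return KnnConfig(k_min=self.k_min, k_max=self.k_max)

    @staticmethod
    def load(path: str | os.PathLike) -> "PipelineConfig":
        path = os.fspath(path)
        if path.endswith(".toml"):
            import tomllib

            with open(path, "rb") as fh:
                raw = tomllib.load(fh)
        else:
            with open(path) as fh:
                raw = json.load(fh)
        return PipelineConfig.from_dict(raw)

    @staticmethod
    def from_dict(raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        svm = SvmConfig(**raw.pop("svm", {}))
        ranker = LambdaMartConfig(**raw.pop("ranker", {}))
        pruning = PruningConfig(**raw.pop("pruning", {}))
        return PipelineConfig(svm=svm, ranker=ranker, pruning=pruning, **raw)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()
             if k not in ("svm", "ranker", "pruning")}
        d["svm"] = dict(self.svm.__dict__)
        d["ranker"] = dict(self.ranker.__dict__)
        d["pruning"] = dict(self.pruning.__dict__)
        return d


@dataclass
class TrainedArtifacts:
    index: SimilarityIndex
    battery: LabelModelBattery
    translation: TranslationTable
    background: BackgroundStats
    ranker: LambdaMARTModel
    config: PipelineConfig


def _missing(path: str, producer: str):
    return FileNotFoundError(
        f"required artifact {path!r} not found; run the {producer!r} step first"
    )


def load_artifacts(out_dir: str | os.PathLike, cfg: PipelineConfig) -> TrainedArtifacts:
    out_dir = os.fspath(out_dir)

    def need(key: str, producer: str) -> str:
        p = os.path.join(out_dir, _ARTIFACTS[key])
        if not os.path.exists(p):
            raise _missing(p, producer)
        return p

    return TrainedArtifacts(
        index=SimilarityIndex.load(need("index", "train")),
        battery=LabelModelBattery.load(need("classifiers", "train")),
        translation=TranslationTable.load(need("translation", "train")),
        background=BackgroundStats.load(need("background", "train")),
        ranker=LambdaMARTModel.load(need("ranker", "train")),
        config=cfg,
    )


def _name_tokens(vocab: Vocabulary, did: str, stemmer: str) -> list[str]:
    return stem_tokens(
        tokenize(vocab.get(did).preferred_name),
        stemmer=stemmer,
        stopwords=DEFAULT_STOPWORDS,
    )


def label_frequencies(corpus: list[Document]) -> dict[str, int]:
    """Annotation counts, one per (document, descriptor)."""
    freq: dict[str, int] = {}
    for d in corpus:
        for t in set(d.gold_terms):
            freq[t] = freq.get(t, 0) + 1
    return freq


def _external_for(doc, cfg: PipelineConfig, vocab, external_map):
    if external_map is not None:
        return external_map.get(doc.doc_id, [])
    if cfg.use_pseudo_external:
        return pseudo_recommender(doc, vocab, top_m=cfg.external_top_m,
                                  stemmer=cfg.stemmer)
    return None


def train(
    corpus: list[Document],
    vocab: Vocabulary,
    cfg: PipelineConfig,
    out_dir: str | os.PathLike,
    external_map: dict[str, list[str]] | None = None,
) -> TrainedArtifacts:
    """Build all artifacts from a gold-annotated training corpus."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    floor = cfg.date_floor_date
    logger.info("building similarity index (date floor %s)", floor)
    index = build_index(corpus, date_floor=floor, stemmer=cfg.stemmer)
    vocab.set_label_frequencies(
        label_frequencies([d for d in corpus if d.doc_id in index.docs])
    )
    index.save(os.path.join(out_dir, _ARTIFACTS["index"]))

    train_docs = [index.docs[did] for did in index.doc_ids]
    gold = index.annotations

    logger.info("training classifier battery (%d labels requested)",
                cfg.n_classifier_labels)
    battery = train_all(
        train_docs, gold, vocab,
        n_labels=min(cfg.n_classifier_labels, len(vocab)),
        cfg=cfg.svm, n_jobs=cfg.n_jobs,
    )
    battery.save(os.path.join(out_dir, _ARTIFACTS["classifiers"]))
    if battery.skipped:
        logger.info("skipped %d untrainable labels", len(battery.skipped))

    logger.info("training translation table")
    pairs = []
    for did in index.doc_ids:
        pdoc = index.docs[did]
        doc_side = sorted(pdoc.tf, key=lambda t: (-pdoc.tf[t], t))
        doc_side = doc_side[: cfg.translation_doc_tokens]
        for term in gold[did]:
            if term in vocab:
                toks = _name_tokens(vocab, term, cfg.stemmer)
                if toks and doc_side:
                    pairs.append((toks, doc_side))
    if len(pairs) > cfg.translation_pairs:
        keep = rng.choice(len(pairs), size=cfg.translation_pairs, replace=False)
        pairs = [pairs[i] for i in sorted(keep)]
    tt = train_ibm1(pairs, iters=cfg.translation_iters, seed=cfg.seed)
    tt.save(os.path.join(out_dir, _ARTIFACTS["translation"]))

    bg_docs = train_docs[: cfg.background_sample]
    bg = background_stats_from_docs(bg_docs)
    bg.save(os.path.join(out_dir, _ARTIFACTS["background"]))

    logger.info("building ranker training lists")
    n_sample = min(cfg.ranker_train_docs, len(train_docs))
    sample_idx = sorted(
        rng.choice(len(train_docs), size=n_sample, replace=False)
    )
    lists = []
    tsv_rows = []
    for i in sample_idx:
        pdoc = train_docs[i]
        neighbours = knn_retrieve(index, pdoc, cfg.knn)
        cands = generate_candidates(
            pdoc, neighbours, gold, battery,
            external=_external_for(pdoc, cfg, vocab, external_map),
        )
        cands = [c for c in cands if c.descriptor_id in vocab]
        if not cands:
            continue
        X = features_for_candidates(
            pdoc, cands, vocab, neighbours, gold, tt, bg, stemmer=cfg.stemmer
        )
        y = np.array(
            [int(c.descriptor_id in gold[pdoc.doc_id]) for c in cands]
        )
        if y.max() > y.min():
            lists.append((X, y))
            for c, label, feats in zip(cands, y, X):
                tsv_rows.append((pdoc.doc_id, c.descriptor_id, label, feats))
    write_candidate_tsv(os.path.join(out_dir, "ranker_train.tsv"), tsv_rows)

    logger.info("training ranker on %d lists", len(lists))
    model = train_lambdamart(lists, cfg.ranker)
    model.save(os.path.join(out_dir, _ARTIFACTS["ranker"]))

    with open(os.path.join(out_dir, "config.json"), "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=1, sort_keys=True)
    return TrainedArtifacts(
        index=index, battery=battery, translation=tt,
        background=bg, ranker=model, config=cfg,
    )


def _predict_one(
    doc: Document,
    arts: TrainedArtifacts,
    vocab: Vocabulary,
    cfg: PipelineConfig,
    external_map,
    age_rules,
    method: str,
) -> PredictionList:
    pdoc = preprocess(doc, stemmer=cfg.stemmer)
    neighbours = knn_retrieve(arts.index, pdoc, cfg.knn)
    annotations = arts.index.annotations
    cands = generate_candidates(
        pdoc, neighbours, annotations, arts.battery,
        external=_external_for(pdoc, cfg, vocab, external_map),
    )
    cands = [c for c in cands if c.descriptor_id in vocab]
    if not cands:
        return PredictionList(doc_id=doc.doc_id, items=[])
    if method == "ranker":
        X = features_for_candidates(
            pdoc, cands, vocab, neighbours, annotations,
            arts.translation, arts.background, stemmer=cfg.stemmer,
        )
        pred = score_candidates(
            arts.ranker, doc.doc_id, [c.descriptor_id for c in cands], X
        )
    elif method == "neighbour-frequency":
        # baseline: rank purely by how often neighbours carry the term
        counts = {}
        simsum = {}
        for nb in neighbours:
            for did in annotations.get(nb.doc_id, []):
                counts[did] = counts.get(did, 0) + 1
                simsum[did] = simsum.get(did, 0.0) + nb.similarity
        items = sorted(
            (c.descriptor_id for c in cands),
            key=lambda d: (-counts.get(d, 0), -simsum.get(d, 0.0), d),
        )
        pred = PredictionList(
            doc_id=doc.doc_id,
            items=[
                ScoredTerm(descriptor_id=d, score=float(counts.get(d, 0)))
                for d in items
            ],
        )
    else:
        raise ValueError(f"unknown prediction method {method!r}")
    return postprocess(pred, doc, vocab, age_rules=age_rules, pruning=cfg.pruning)


def predict(
    docs: list[Document],
    vocab: Vocabulary,
    arts: TrainedArtifacts,
    cfg: PipelineConfig,
    external_map: dict[str, list[str]] | None = None,
    method: str = "ranker",
) -> list[PredictionList]:
    """Ranked, pruned predictions for *docs* (order-preserving)."""
    age_rules = default_age_rules(vocab)
    preds = Parallel(n_jobs=cfg.n_jobs)(
        delayed(_predict_one)(
            doc, arts, vocab, cfg, external_map, age_rules, method
        )
        for doc in docs
    )
    return list(preds)


def write_predictions_tsv(
    preds: list[PredictionList], vocab: Vocabulary, path: str | os.PathLike
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("doc_id\trank\tdescriptor_id\tpreferred_name\tscore\n")
        for pl in preds:
            for rank, it in enumerate(pl.items, start=1):
                name = vocab.get(it.descriptor_id).preferred_name
                fh.write(
                    f"{pl.doc_id}\t{rank}\t{it.descriptor_id}\t{name}"
                    f"\t{it.score:.10g}\n"
                )


def write_predictions_json(
    preds: list[PredictionList], path: str | os.PathLike
) -> None:
    payload = {
        "documents": [
            {"pmid": pl.doc_id, "labels": pl.ids()} for pl in preds
        ]
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def evaluate_predictions(
    preds: list[PredictionList], docs: list[Document]
) -> EvalReport:
    gold = {d.doc_id: set(d.gold_terms) for d in docs}
    predicted = {pl.doc_id: set(pl.ids()) for pl in preds}
    return evaluate_corpus(predicted, gold)


def run_pipeline(
    corpus_path: str | os.PathLike,
    vocab_path: str | os.PathLike,
    config_path: str | os.PathLike | None,
    mode: str,
    out_dir: str | os.PathLike = "artifacts",
    vocab_dialect: str = "tsv",
    external_path: str | os.PathLike | None = None,
    method: str = "ranker",
):
    """CLI-facing entry point covering train / predict / evaluate."""
    cfg = PipelineConfig.load(config_path) if config_path else PipelineConfig()
    logger.info("mode=%s seed=%d config=%s", mode, cfg.seed, config_path)
    vocab = load_vocabulary(vocab_path, dialect=vocab_dialect)
    docs = load_corpus(corpus_path)
    external_map = read_external_tsv(external_path) if external_path else None
    out_dir = os.fspath(out_dir)

    if mode == "train":
        return train(docs, vocab, cfg, out_dir, external_map=external_map)
    if mode in ("predict", "evaluate"):
        # label frequencies are an index-time property; restore for queries
        vocab.set_label_frequencies(label_frequencies(docs))
        arts = load_artifacts(out_dir, cfg)
        preds = predict(docs, vocab, arts, cfg,
                        external_map=external_map, method=method)
        write_predictions_tsv(
            preds, vocab, os.path.join(out_dir, "predictions.tsv")
        )
        write_predictions_json(preds, os.path.join(out_dir, "predictions.json"))
        if mode == "evaluate":
            report = evaluate_predictions(preds, docs)
            report.save(os.path.join(out_dir, "evaluation.json"))
            return report
        return preds
    raise ValueError(f"unknown mode {mode!r}")
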