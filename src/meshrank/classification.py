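"""Per-label cost-sensitive linear classifiers (candidate source #2).

Each frequent label gets its own binary classifier over L2-normalized
stemmed-unigram term frequencies.  The objective is a cost-sensitive
SVM with the modified Huber loss:

    (λ/2)‖w‖² + C₊ Σ_{y=+1} h(y(θ + w·x)) + C₋ Σ_{y=−1} h(y(θ + w·x))

with C₊ = r·C₋ (default r = 1.5) so that the scarce positive class
carries a higher misclassification cost than the abundant negative
class.  h is quadratic inside the margin and linear for badly
misclassified points, which keeps gradients bounded on noisy data:

    h(z) = −4z        for z ≤ −1
    h(z) = (1 − z)²   for −1 < z < 1
    h(z) = 0          for z ≥ 1

Training is stochastic gradient descent with inverse-t decay (seeded,
deterministic), or full-batch descent with backtracking line search
when a monotone cost trajectory is wanted.  The decision value
θ + w·x is kept as a ranking feature even for terms the classifier
does not fire on.
"""

from __future__ import annotations

import json
import math
import os
import zlib
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed

from .corpus import ProcessedDoc
from .vocabulary import Vocabulary, top_frequent_labels


@dataclass
class SvmConfig:
    reg_lambda: float = 1e-4
    cost_ratio_r: float = 1.5
    c_minus: float = 1.0
    epochs: int = 10
    learning_rate_schedule: str = "inv-t"
    learning_rate: float = 0.5
    batch_mode: str = "sgd"  # "sgd" | "full"
    negative_cap_ratio: float = 10.0  # negatives kept per positive in train_all
    seed: int = 0

    def __post_init__(self):
        if self.cost_ratio_r <= 0:
            raise ValueError("cost_ratio_r must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate_schedule != "inv-t":
            raise ValueError(
                f"unknown learning-rate schedule {self.learning_rate_schedule!r}"
            )

    @property
    def c_plus(self) -> float:
        return self.cost_ratio_r * self.c_minus


@dataclass
class LabelModel:
    descriptor_id: str
    w: dict[str, float] = field(default_factory=dict)
    theta: float = 0.0


def huber_loss(z: float) -> float:
    """Modified Huber loss h(z); continuous, convex, zero for z ≥ 1."""
    if z <= -1.0:
        return -4.0 * z
    if z < 1.0:
        return (1.0 - z) ** 2
    return 0.0


def _huber_grad(z: float) -> float:
    """dh/dz (continuous at both knots)."""
    if z <= -1.0:
        return -4.0
    if z < 1.0:
        return -2.0 * (1.0 - z)
    return 0.0


def doc_features(doc: ProcessedDoc) -> dict[str, float]:
    """L2-normalized term-frequency vector of a processed document."""
    if not doc.tf:
        return {}
    norm = math.sqrt(sum(c * c for c in doc.tf.values()))
    return {t: c / norm for t, c in doc.tf.items()}


def predict_score(model: LabelModel, doc: ProcessedDoc) -> float:
    """Decision value θ + w·x; positive classification iff > 0."""
    x = doc_features(doc)
    return model.theta + sum(model.w.get(t, 0.0) * v for t, v in x.items())


def cost(
    model: LabelModel,
    data: list[tuple[dict[str, float], int]],
    cfg: SvmConfig,
) -> float:
    """Evaluate the cost-sensitive objective on labelled feature maps."""
    reg = 0.5 * cfg.reg_lambda * sum(v * v for v in model.w.values())
    total = reg
    for x, y in data:
        if y not in (-1, 1):
            raise ValueError(f"labels must be in {{-1, +1}}, got {y}")
        z = y * (model.theta + sum(model.w.get(t, 0.0) * v for t, v in x.items()))
        total += (cfg.c_plus if y == 1 else cfg.c_minus) * huber_loss(z)
    return total


def cost_gradient(
    model: LabelModel,
    data: list[tuple[dict[str, float], int]],
    cfg: SvmConfig,
) -> tuple[dict[str, float], float]:
    """Analytic full-batch gradient of :func:`cost` wrt (w, θ)."""
    grad_w = {t: cfg.reg_lambda * v for t, v in model.w.items()}
    grad_theta = 0.0
    for x, y in data:
        z = y * (model.theta + sum(model.w.get(t, 0.0) * v for t, v in x.items()))
        g = _huber_grad(z) * y
        if g == 0.0:
            continue
        coeff = cfg.c_plus if y == 1 else cfg.c_minus
        for t, v in x.items():
            grad_w[t] = grad_w.get(t, 0.0) + coeff * g * v
        grad_theta += coeff * g
    return grad_w, grad_theta


def _to_arrays(data, vocab_index):
    rows = []
    for x, y in data:
        idx = np.fromiter((vocab_index[t] for t in x), dtype=np.int64, count=len(x))
        val = np.fromiter(x.values(), dtype=np.float64, count=len(x))
        rows.append((idx, val, y))
    return rows


def train_label_model(
    label: str,
    corpus: list[ProcessedDoc],
    cfg: SvmConfig,
    gold: dict[str, list[str]] | None = None,
) -> LabelModel:
    """Fit one label's classifier by minimizing the cost objective.

    *gold* maps doc_id → gold descriptor list; when omitted, documents
    must carry a ``gold_terms`` attribute.  Requires at least one
    positive and one negative example.
    """
    data: list[tuple[dict[str, float], int]] = []
    for doc in corpus:
        terms = gold[doc.doc_id] if gold is not None else getattr(doc, "gold_terms")
        y = 1 if label in terms else -1
        data.append((doc_features(doc), y))
    labels = {y for _, y in data}
    if labels != {-1, 1}:
        raise ValueError(
            f"label {label!r}: training data is single-class ({sorted(labels)})"
        )
    return _fit(label, data, cfg)


def _fit(
    label: str, data: list[tuple[dict[str, float], int]], cfg: SvmConfig
) -> LabelModel:
    vocab_index: dict[str, int] = {}
    for x, _ in data:
        for t in x:
            if t not in vocab_index:
                vocab_index[t] = len(vocab_index)
    rows = _to_arrays(data, vocab_index)
    m = len(vocab_index)
    w = np.zeros(m)
    theta = 0.0
    rng = np.random.default_rng(cfg.seed)

    if cfg.batch_mode == "full":
        w, theta = _fit_full_batch(rows, w, theta, cfg)
    else:
        n = len(rows)
        t_step = 0
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            for i in order:
                idx, val, y = rows[i]
                eta = cfg.learning_rate / (1.0 + t_step / n)
                z = y * (theta + float(w[idx] @ val))
                g = _huber_grad(z) * y
                coeff = cfg.c_plus if y == 1 else cfg.c_minus
                # regularizer applied stochastically at 1/n scale
                w *= 1.0 - eta * cfg.reg_lambda
                if g != 0.0:
                    w[idx] -= eta * coeff * g * val
                    theta -= eta * coeff * g
                t_step += 1

    model = LabelModel(descriptor_id=label, theta=float(theta))
    inv = {j: t for t, j in vocab_index.items()}
    model.w = {inv[j]: float(w[j]) for j in np.nonzero(w)[0]}
    return model


def _cost_arrays(rows, w, theta, cfg):
    total = 0.5 * cfg.reg_lambda * float(w @ w)
    for idx, val, y in rows:
        z = y * (theta + float(w[idx] @ val))
        total += (cfg.c_plus if y == 1 else cfg.c_minus) * huber_loss(z)
    return total


def _fit_full_batch(rows, w, theta, cfg):
    """Gradient descent with backtracking: cost never increases."""
    step = cfg.learning_rate
    current = _cost_arrays(rows, w, theta, cfg)
    for _ in range(cfg.epochs):
        gw = cfg.reg_lambda * w.copy()
        gt = 0.0
        for idx, val, y in rows:
            z = y * (theta + float(w[idx] @ val))
            g = _huber_grad(z) * y
            if g != 0.0:
                coeff = cfg.c_plus if y == 1 else cfg.c_minus
                gw[idx] += coeff * g * val
                gt += coeff * g
        # backtrack until descent (objective is convex and smooth)
        while step > 1e-12:
            w_new = w - step * gw
            t_new = theta - step * gt
            new = _cost_arrays(rows, w_new, t_new, cfg)
            if new <= current:
                w, theta, current = w_new, t_new, new
                break
            step *= 0.5
    return w, theta


def _label_seed(base_seed: int, label: str) -> int:
    return (base_seed * 1_000_003 + zlib.crc32(label.encode())) % (2**31 - 1)


def _train_one(label, corpus, gold, cfg):
    """Self-contained per-label training task (worker-count independent)."""
    positives = [d for d in corpus if label in gold[d.doc_id]]
    negatives = [d for d in corpus if label not in gold[d.doc_id]]
    if not positives:
        return label, None, "no positive examples"
    if not negatives:
        return label, None, "no negative examples"
    seed = _label_seed(cfg.seed, label)
    cap = int(cfg.negative_cap_ratio * len(positives))
    if cap and len(negatives) > cap:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(negatives), size=cap, replace=False)
        negatives = [negatives[i] for i in sorted(keep)]
    data = [(doc_features(d), 1) for d in positives]
    data += [(doc_features(d), -1) for d in negatives]
    local_cfg = SvmConfig(**{**cfg.__dict__, "seed": seed})
    return label, _fit(label, data, local_cfg), None


@dataclass
class LabelModelBattery:
    """Trained per-label models plus the labels skipped (with reasons)."""

    models: dict[str, LabelModel]
    skipped: dict[str, str]
    config: SvmConfig
    vocab_hash: str = ""

    def predict_positive(self, doc: ProcessedDoc) -> list[str]:
        return sorted(lbl for lbl, s in self.scores(doc).items() if s > 0)

    def _weight_matrix(self):
        """Cached (labels, token index, CSR weights, thetas) stack."""
        cached = getattr(self, "_mat", None)
        if cached is None:
            import scipy.sparse as sp

            labels = sorted(self.models)
            tok_index: dict[str, int] = {}
            rows, cols, vals = [], [], []
            for i, lbl in enumerate(labels):
                for t, v in self.models[lbl].w.items():
                    j = tok_index.setdefault(t, len(tok_index))
                    rows.append(i)
                    cols.append(j)
                    vals.append(v)
            mat = sp.csr_matrix(
                (vals, (rows, cols)), shape=(len(labels), max(len(tok_index), 1))
            )
            thetas = np.array([self.models[lbl].theta for lbl in labels])
            cached = (labels, tok_index, mat, thetas)
            self._mat = cached
        return cached

    def scores(self, doc: ProcessedDoc) -> dict[str, float]:
        """Decision values θ + w·x for every trained label at once."""
        labels, tok_index, mat, thetas = self._weight_matrix()
        x = np.zeros(mat.shape[1])
        feats = doc_features(doc)
        for t, v in feats.items():
            j = tok_index.get(t)
            if j is not None:
                x[j] = v
        s = thetas + mat @ x
        return {lbl: float(s[i]) for i, lbl in enumerate(labels)}

    # -- persistence: one sparse-weight record per label + manifest ------

    def save(self, directory: str | os.PathLike) -> None:
        directory = os.fspath(directory)
        os.makedirs(directory, exist_ok=True)
        manifest = {
            "config": self.config.__dict__,
            "vocab_hash": self.vocab_hash,
            "labels": sorted(self.models),
            "skipped": self.skipped,
        }
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        with open(os.path.join(directory, "weights.jsonl"), "w") as fh:
            for lbl in sorted(self.models):
                m = self.models[lbl]
                fh.write(
                    json.dumps(
                        {
                            "label": lbl,
                            "theta": m.theta,
                            "w": {t: m.w[t] for t in sorted(m.w)},
                        }
                    )
                    + "\n"
                )

    @staticmethod
    def load(directory: str | os.PathLike) -> "LabelModelBattery":
        directory = os.fspath(directory)
        with open(os.path.join(directory, "manifest.json")) as fh:
            manifest = json.load(fh)
        models = {}
        with open(os.path.join(directory, "weights.jsonl")) as fh:
            for line in fh:
                rec = json.loads(line)
                models[rec["label"]] = LabelModel(
                    descriptor_id=rec["label"], w=rec["w"], theta=rec["theta"]
                )
        return LabelModelBattery(
            models=models,
            skipped=manifest["skipped"],
            config=SvmConfig(**manifest["config"]),
            vocab_hash=manifest.get("vocab_hash", ""),
        )


def train_all(
    corpus: list[ProcessedDoc],
    gold: dict[str, list[str]],
    vocab: Vocabulary,
    n_labels: int,
    cfg: SvmConfig,
    n_jobs: int = 1,
) -> LabelModelBattery:
    """Train classifiers for the *n_labels* most frequent labels.

    Labels with no positive (or no negative) documents are skipped and
    reported.  Results are independent of ``n_jobs``: every label's
    subsampling and SGD seed derives from the label name, not from
    scheduling order.
    """
    if n_labels < 1:
        raise ValueError("n_labels must be >= 1")
    labels = top_frequent_labels(vocab, n_labels)
    results = Parallel(n_jobs=n_jobs)(
        delayed(_train_one)(lbl, corpus, gold, cfg) for lbl in labels
    )
    models: dict[str, LabelModel] = {}
    skipped: dict[str, str] = {}
    for lbl, model, reason in results:
        if model is None:
            skipped[lbl] = reason
        else:
            models[lbl] = model
    import hashlib

    vhash = hashlib.sha256(
        "\x1f".join(sorted(vocab.descriptors)).encode()
    ).hexdigest()[:16]
    return LabelModelBattery(
        models=models, skipped=skipped, config=cfg, vocab_hash=vhash
    )
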