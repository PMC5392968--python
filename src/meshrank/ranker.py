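"""LambdaMART learning-to-rank over candidate feature vectors.

The ranker is a gradient-boosted ensemble of limited-leaf regression
trees.  Each boosting round computes, per candidate list, the lambda
pseudo-gradients — pairwise sigmoid terms weighted by the NDCG change
that swapping the pair would cause — fits a tree to them by greedy
variance-reduction splitting, sets leaf values with a Newton step
(sum of lambdas over sum of hessian weights), and adds the tree with a
shrinkage factor.  Relevance is binary (a candidate either was or was
not manually assigned), so NDCG gains are 2^y − 1 ∈ {0, 1}.
"""

from __future__ import annotations

import heapq
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .features import FEATURE_NAMES, feature_schema_hash


# ---------------------------------------------------------------------------
# NDCG
# ---------------------------------------------------------------------------

def _dcg(labels, k: int) -> float:
    return sum(
        (2.0 ** y - 1.0) / math.log2(pos + 2)
        for pos, y in enumerate(labels[:k])
    )


def ndcg_at(ranking: list[int], k: int) -> float:
    """NDCG@k of a ranked 0/1 relevance list.

    Gain 2^y − 1, discount 1/log2(position + 1) with 1-based positions.
    Lists with no relevant item score 1.0 by convention (the ideal DCG
    is zero; nothing could have been ranked better).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ideal = _dcg(sorted(ranking, reverse=True), k)
    if ideal == 0:
        return 1.0
    return _dcg(ranking, k) / ideal


# ---------------------------------------------------------------------------
# Lambda gradients
# ---------------------------------------------------------------------------

def lambda_gradients(
    scores, labels, sigma: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise lambda pseudo-gradients and hessian weights for one list.

    Items are ranked by current score (descending, ties by index).  For
    every pair with label_i > label_j:

        ρ   = 1 / (1 + exp(σ(s_i − s_j)))
        λ_i += σ·ρ·|ΔNDCG_ij|        λ_j −= σ·ρ·|ΔNDCG_ij|
        h_i += σ²·ρ(1−ρ)·|ΔNDCG_ij|  h_j likewise

    where |ΔNDCG_ij| is the NDCG change from swapping the two items'
    positions in the current ordering (truncation at list length).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n = scores.size
    lambdas = np.zeros(n)
    hessians = np.zeros(n)
    if n < 2:
        return lambdas, hessians

    order = sorted(range(n), key=lambda i: (-scores[i], i))
    rank_of = np.empty(n, dtype=np.int64)  # 0-based position in ranking
    for pos, i in enumerate(order):
        rank_of[i] = pos
    ideal = _dcg(sorted(labels.tolist(), reverse=True), n)
    if ideal == 0:
        return lambdas, hessians
    inv_disc = 1.0 / np.log2(np.arange(n) + 2.0)

    # binary relevance: all (more, less) pairs are (positive, negative)
    if not set(np.unique(labels)).issubset({0, 1}):
        raise ValueError("labels must be binary {0, 1}")
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    if pos_idx.size == 0 or neg_idx.size == 0:
        return lambdas, hessians

    disc_diff = (
        inv_disc[rank_of[pos_idx]][:, None] - inv_disc[rank_of[neg_idx]][None, :]
    )
    delta = np.abs(disc_diff) / ideal  # gain difference is exactly 1
    s_diff = scores[pos_idx][:, None] - scores[neg_idx][None, :]
    rho = 1.0 / (1.0 + np.exp(sigma * s_diff))
    lam = sigma * rho * delta
    lambdas[pos_idx] += lam.sum(axis=1)
    lambdas[neg_idx] -= lam.sum(axis=0)
    w = sigma * sigma * rho * (1.0 - rho) * delta
    hessians[pos_idx] += w.sum(axis=1)
    hessians[neg_idx] += w.sum(axis=0)
    return lambdas, hessians


# ---------------------------------------------------------------------------
# Regression trees
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    feature: int | None = None
    threshold: float | None = None
    left: "_Node | None" = None
    right: "_Node | None" = None
    value: float = 0.0

    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class RegressionTree:
    root: _Node
    n_leaves: int

    def predict_one(self, x: np.ndarray) -> float:
        node = self.root
        while not node.is_leaf():
            node = node.left if x[node.feature] <= node.threshold else node.right
        return node.value

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(X.shape[0])
        stack = [(self.root, np.arange(X.shape[0]))]
        while stack:
            node, idx = stack.pop()
            if idx.size == 0:
                continue
            if node.is_leaf():
                out[idx] = node.value
            else:
                mask = X[idx, node.feature] <= node.threshold
                stack.append((node.left, idx[mask]))
                stack.append((node.right, idx[~mask]))
        return out

    def split_features(self) -> set[int]:
        out: set[int] = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf():
                out.add(node.feature)
                stack.extend([node.left, node.right])
        return out

    def to_dict(self) -> dict:
        def rec(node: _Node) -> dict:
            if node.is_leaf():
                return {"value": node.value}
            return {
                "feature": node.feature,
                "threshold": node.threshold,
                "left": rec(node.left),
                "right": rec(node.right),
            }

        return {"n_leaves": self.n_leaves, "root": rec(self.root)}

    @staticmethod
    def from_dict(d: dict) -> "RegressionTree":
        def rec(rd: dict) -> _Node:
            if "value" in rd:
                return _Node(value=rd["value"])
            return _Node(
                feature=rd["feature"],
                threshold=rd["threshold"],
                left=rec(rd["left"]),
                right=rec(rd["right"]),
            )

        return RegressionTree(root=rec(d["root"]), n_leaves=d["n_leaves"])


def _best_split(X, target, idx, min_leaf_obs):
    """Best (feature, threshold) by squared-error reduction on idx.

    Vectorized over cut positions; ties resolved toward the lowest
    feature index (and, within a feature, the first qualifying cut in
    sorted order) so tree structure is deterministic.
    """
    best = None  # (gain, feature, threshold)
    t_sub = target[idx]
    n = idx.size
    if n < 2 * min_leaf_obs:
        return None
    total_sum = t_sub.sum()
    total_sq = (t_sub**2).sum()
    base_err = total_sq - total_sum**2 / n
    for f in range(X.shape[1]):
        vals = X[idx, f]
        order = np.argsort(vals, kind="stable")
        v_sorted = vals[order]
        t_sorted = t_sub[order]
        csum = np.cumsum(t_sorted)
        csq = np.cumsum(t_sorted**2)
        # candidate cut after position p (left = 0..p), p in valid window
        p = np.arange(min_leaf_obs - 1, n - min_leaf_obs)
        if p.size == 0:
            continue
        valid = v_sorted[p] != v_sorted[p + 1]
        if not np.any(valid):
            continue
        nl = (p + 1).astype(np.float64)
        nr = n - nl
        sl, ssl = csum[p], csq[p]
        sr, ssr = total_sum - sl, total_sq - ssl
        err = (ssl - sl**2 / nl) + (ssr - sr**2 / nr)
        gain = np.where(valid, base_err - err, -np.inf)
        pb = int(np.argmax(gain))
        g = float(gain[pb])
        if g > 1e-12 and (best is None or g > best[0] + 1e-15):
            thr = 0.5 * (v_sorted[p[pb]] + v_sorted[p[pb] + 1])
            best = (g, f, float(thr))
    return best


def _fit_tree(
    X: np.ndarray,
    lambdas: np.ndarray,
    hessians: np.ndarray,
    max_leaves: int,
    min_leaf_obs: int,
) -> RegressionTree:
    """Greedy best-first tree on the lambda targets; Newton leaf values."""
    n = X.shape[0]
    root = _Node()
    all_idx = np.arange(n)

    def leaf_value(idx):
        denom = hessians[idx].sum()
        if denom <= 1e-12:
            return 0.0
        return float(lambdas[idx].sum() / denom)

    root.value = leaf_value(all_idx)
    # heap of candidate splits: (-gain, insertion order, node, idx, split)
    heap = []
    counter = 0

    def push(node, idx):
        nonlocal counter
        split = _best_split(X, lambdas, idx, min_leaf_obs)
        if split is not None:
            heapq.heappush(heap, (-split[0], counter, node, idx, split))
            counter += 1

    push(root, all_idx)
    n_leaves = 1
    while heap and n_leaves < max_leaves:
        _, _, node, idx, (gain, f, thr) = heapq.heappop(heap)
        mask = X[idx, f] <= thr
        left_idx, right_idx = idx[mask], idx[~mask]
        node.feature, node.threshold = f, thr
        node.left = _Node(value=leaf_value(left_idx))
        node.right = _Node(value=leaf_value(right_idx))
        node.value = 0.0
        n_leaves += 1
        push(node.left, left_idx)
        push(node.right, right_idx)
    return RegressionTree(root=root, n_leaves=n_leaves)


# ---------------------------------------------------------------------------
# LambdaMART
# ---------------------------------------------------------------------------

@dataclass
class LambdaMartConfig:
    n_trees: int = 300
    max_leaves: int = 10
    learning_rate: float = 0.1
    min_leaf_obs: int = 1
    sigma: float = 1.0
    seed: int = 0


@dataclass
class LambdaMARTModel:
    trees: list[RegressionTree]
    learning_rate: float
    schema_hash: str = field(default_factory=feature_schema_hash)
    metadata: dict = field(default_factory=dict)

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        out = np.zeros(X.shape[0])
        for tree in self.trees:
            out += self.learning_rate * tree.predict(X)
        return out

    def save(self, path: str | os.PathLike) -> None:
        payload = {
            "schema_hash": self.schema_hash,
            "feature_names": list(FEATURE_NAMES),
            "learning_rate": self.learning_rate,
            "metadata": self.metadata,
            "trees": [t.to_dict() for t in self.trees],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True)

    @staticmethod
    def load(path: str | os.PathLike) -> "LambdaMARTModel":
        with open(path) as fh:
            payload = json.load(fh)
        return LambdaMARTModel(
            trees=[RegressionTree.from_dict(t) for t in payload["trees"]],
            learning_rate=payload["learning_rate"],
            schema_hash=payload["schema_hash"],
            metadata=payload.get("metadata", {}),
        )


def train_lambdamart(
    training_lists: list[tuple[np.ndarray, np.ndarray]],
    cfg: LambdaMartConfig | None = None,
) -> LambdaMARTModel:
    """Boost regression trees against lambda gradients.

    *training_lists* holds (features n×d, binary labels n) per
    document.  Lists without both a positive and a negative label
    produce no pairwise gradients; at least one mixed list is required.
    """
    cfg = cfg or LambdaMartConfig()
    lists = [
        (np.asarray(X, dtype=np.float64), np.asarray(y, dtype=np.int64))
        for X, y in training_lists
        if len(y) > 0
    ]
    if not any((y.max() > y.min()) for _, y in lists if y.size):
        raise ValueError("no training list contains both labels")

    X_all = np.vstack([X for X, _ in lists])
    offsets = np.cumsum([0] + [len(y) for _, y in lists])
    scores = np.zeros(X_all.shape[0])
    trees: list[RegressionTree] = []

    for _ in range(cfg.n_trees):
        lambdas = np.zeros_like(scores)
        hessians = np.zeros_like(scores)
        for li, (_, y) in enumerate(lists):
            lo, hi = offsets[li], offsets[li + 1]
            lam, hes = lambda_gradients(scores[lo:hi], y, sigma=cfg.sigma)
            lambdas[lo:hi] = lam
            hessians[lo:hi] = hes
        if not np.any(lambdas):
            break
        tree = _fit_tree(
            X_all, lambdas, hessians, cfg.max_leaves, cfg.min_leaf_obs
        )
        trees.append(tree)
        scores += cfg.learning_rate * tree.predict(X_all)

    return LambdaMARTModel(
        trees=trees,
        learning_rate=cfg.learning_rate,
        metadata={
            "n_trees": len(trees),
            "max_leaves": cfg.max_leaves,
            "min_leaf_obs": cfg.min_leaf_obs,
            "sigma": cfg.sigma,
            "seed": cfg.seed,
            "n_lists": len(lists),
        },
    )


def mean_train_ndcg(
    model: LambdaMARTModel,
    lists: list[tuple[np.ndarray, np.ndarray]],
    k: int = 10,
) -> float:
    vals = []
    for X, y in lists:
        s = model.score(np.asarray(X))
        order = sorted(range(len(y)), key=lambda i: (-s[i], i))
        vals.append(ndcg_at([int(y[i]) for i in order], k))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Scoring candidate lists
# ---------------------------------------------------------------------------

@dataclass
class ScoredTerm:
    descriptor_id: str
    score: float


@dataclass
class PredictionList:
    """Ordered, scored descriptor predictions for one document."""

    doc_id: str
    items: list[ScoredTerm]

    def ids(self) -> list[str]:
        return [it.descriptor_id for it in self.items]


def score_candidates(
    model: LambdaMARTModel,
    doc_id: str,
    candidate_ids: list[str],
    features: np.ndarray,
    schema_hash: str | None = None,
) -> PredictionList:
    """Score and order one candidate list (desc score, ties by id)."""
    expected = schema_hash or feature_schema_hash()
    if model.schema_hash != expected:
        raise ValueError(
            f"feature schema mismatch: model {model.schema_hash!r} "
            f"vs expected {expected!r}"
        )
    if not candidate_ids:
        return PredictionList(doc_id=doc_id, items=[])
    scores = model.score(features)
    order = sorted(
        range(len(candidate_ids)),
        key=lambda i: (-scores[i], candidate_ids[i]),
    )
    return PredictionList(
        doc_id=doc_id,
        items=[
            ScoredTerm(descriptor_id=candidate_ids[i], score=float(scores[i]))
            for i in order
        ],
    )
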