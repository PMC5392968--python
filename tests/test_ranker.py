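"""NDCG, lambda gradients, tree boosting and candidate scoring."""

import itertools
import math

import numpy as np
import pytest

from meshrank import (
    LambdaMartConfig,
    LambdaMARTModel,
    PredictionList,
    lambda_gradients,
    ndcg_at,
    score_candidates,
    train_lambdamart,
)
from meshrank.ranker import _dcg, mean_train_ndcg


class TestNdcg:
    @pytest.mark.parametrize(
        "labels,k,expected",
        [
            ([1, 0, 0], 3, 1.0),                      # ideal order
            ([0, 1], 2, 1.0 / math.log2(3)),           # hand computation
            ([0, 0], 5, 1.0),                          # no relevant: convention
            ([1, 1], 2, 1.0),
            ([0, 0, 1], 1, 0.0),                       # relevant below the cut
        ],
    )
    def test_examples(self, labels, k, expected):
        assert ndcg_at(labels, k) == pytest.approx(expected)

    def test_bounded_and_one_iff_ideal_over_all_permutations(self):
        for n in (2, 3, 4, 5, 6):
            base = [1] * (n // 2) + [0] * (n - n // 2)
            for perm in set(itertools.permutations(base)):
                val = ndcg_at(list(perm), n)
                assert 0.0 <= val <= 1.0 + 1e-12
                is_ideal = list(perm) == sorted(perm, reverse=True)
                assert (val == pytest.approx(1.0)) == is_ideal

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            ndcg_at([1, 0], 0)


def _ndcg_of_order(labels_in_rank_order):
    n = len(labels_in_rank_order)
    ideal = _dcg(sorted(labels_in_rank_order, reverse=True), n)
    if ideal == 0:
        return 1.0
    return _dcg(labels_in_rank_order, n) / ideal


class TestLambdaGradients:
    def test_single_pair_brute_force(self):
        labels = [1, 0]
        scores = [0.0, 0.0]
        lam, hes = lambda_gradients(scores, labels, sigma=1.0)
        # ranking is [item0, item1]; swapping gives |ΔNDCG|
        delta = abs(_ndcg_of_order([1, 0]) - _ndcg_of_order([0, 1]))
        c = 1.0 * 0.5 * delta  # rho = 0.5 at equal scores
        assert lam[0] == pytest.approx(c)
        assert lam[1] == pytest.approx(-c)
        assert hes[0] == pytest.approx(0.25 * delta)

    def test_uniform_labels_give_zero_gradients(self):
        lam, hes = lambda_gradients([0.3, 0.1, 0.9], [1, 1, 1])
        assert not lam.any() and not hes.any()
        lam0, _ = lambda_gradients([0.3, 0.1], [0, 0])
        assert not lam0.any()

    def test_lambda_sum_is_zero_per_list(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(2, 12))
            labels = rng.integers(0, 2, size=n)
            scores = rng.normal(size=n)
            lam, _ = lambda_gradients(scores, labels)
            assert lam.sum() == pytest.approx(0.0, abs=1e-12)

    def test_delta_ndcg_matches_explicit_swap_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            n = 6
            labels = rng.integers(0, 2, size=n)
            if labels.max() == labels.min():
                continue
            scores = rng.normal(size=n)
            order = sorted(range(n), key=lambda i: (-scores[i], i))
            ranked_labels = [int(labels[i]) for i in order]
            pos_of = {item: p for p, item in enumerate(order)}
            for i in range(n):
                for j in range(n):
                    if labels[i] <= labels[j]:
                        continue
                    swapped = list(ranked_labels)
                    pi, pj = pos_of[i], pos_of[j]
                    swapped[pi], swapped[pj] = swapped[pj], swapped[pi]
                    expected = abs(
                        _ndcg_of_order(ranked_labels) - _ndcg_of_order(swapped)
                    )
                    # recover the implementation's delta from a unit pair
                    lam, _ = lambda_gradients(
                        [scores[i], scores[j]], [1, 0], sigma=1.0
                    )
                    # cross-check full-list lambdas by re-deriving pairwise
                    disc = 1.0 / np.log2(np.arange(n) + 2.0)
                    ideal = _dcg(sorted(labels.tolist(), reverse=True), n)
                    impl_delta = abs(disc[pi] - disc[pj]) / ideal
                    assert impl_delta == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lambda_gradients([0.1], [1, 0])


def _separable_lists(rng, n_lists=20, n_items=10, feat=3, d=8):
    lists = []
    for _ in range(n_lists):
        X = rng.uniform(size=(n_items, d))
        y = (X[:, feat] > 0.5).astype(int)
        if y.max() == y.min():
            y[0] = 1 - y[0]
            X[0, feat] = 1.0 - X[0, feat]
        lists.append((X, y))
    return lists


class TestTraining:
    def test_single_feature_separable_reaches_perfect_ndcg(self):
        rng = np.random.default_rng(0)
        lists = _separable_lists(rng)
        model = train_lambdamart(lists, LambdaMartConfig(n_trees=50))
        assert mean_train_ndcg(model, lists, k=10) == pytest.approx(1.0)

    def test_constant_feature_never_split_and_ignored(self):
        rng = np.random.default_rng(1)
        lists = []
        for X, y in _separable_lists(rng, n_lists=10):
            X = X.copy()
            X[:, 7] = 0.7  # constant everywhere
            lists.append((X, y))
        model = train_lambdamart(lists, LambdaMartConfig(n_trees=20))
        used = set()
        for t in model.trees:
            used |= t.split_features()
        assert 7 not in used
        # monotone transform of the unused feature leaves scores unchanged
        X0 = lists[0][0]
        X_t = X0.copy()
        X_t[:, 7] = np.exp(3.0 * X_t[:, 7]) + 1.0
        assert np.array_equal(model.score(X0), model.score(X_t))

    def test_training_ndcg_non_decreasing_over_boosting(self):
        rng = np.random.default_rng(2)
        lists = _separable_lists(rng, n_lists=10)
        vals = []
        for n_trees in (1, 5, 15, 40):
            model = train_lambdamart(lists, LambdaMartConfig(n_trees=n_trees))
            vals.append(mean_train_ndcg(model, lists, k=10))
        assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_two_feature_recovery_on_held_out_lists(self):
        rng = np.random.default_rng(12)

        def make(n_lists):
            lists = []
            for _ in range(n_lists):
                X = rng.uniform(size=(15, 8))
                util = 1.0 * X[:, 1] + 2.0 * X[:, 4]
                y = (util > np.median(util)).astype(int)
                lists.append((X, y))
            return lists

        train = make(40)
        model = train_lambdamart(train, LambdaMartConfig(n_trees=120))
        held_out = make(20)
        assert mean_train_ndcg(model, held_out, k=10) >= 0.95

    def test_same_seed_and_data_bit_identical(self):
        rng1 = np.random.default_rng(5)
        rng2 = np.random.default_rng(5)
        m1 = train_lambdamart(_separable_lists(rng1), LambdaMartConfig(n_trees=10))
        m2 = train_lambdamart(_separable_lists(rng2), LambdaMartConfig(n_trees=10))
        assert [t.to_dict() for t in m1.trees] == [t.to_dict() for t in m2.trees]

    def test_degenerate_training_rejected(self):
        X = np.zeros((3, 4))
        with pytest.raises(ValueError):
            train_lambdamart([(X, np.array([1, 1, 1]))])

    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        lists = _separable_lists(rng, n_lists=5)
        model = train_lambdamart(lists, LambdaMartConfig(n_trees=5))
        model.save(tmp_path / "m.json")
        loaded = LambdaMARTModel.load(tmp_path / "m.json")
        X = lists[0][0]
        assert np.allclose(loaded.score(X), model.score(X))
        assert loaded.schema_hash == model.schema_hash


class TestScoreCandidates:
    def _model(self):
        rng = np.random.default_rng(0)
        d = 11
        lists = []
        for _ in range(5):
            X = rng.uniform(size=(8, d))
            y = (X[:, 0] > 0.5).astype(int)
            if y.max() == y.min():
                y[0] = 1 - y[0]
            lists.append((X, y))
        return train_lambdamart(lists, LambdaMartConfig(n_trees=10))

    def test_empty_candidate_list(self):
        pred = score_candidates(self._model(), "d1", [], np.zeros((0, 11)))
        assert pred == PredictionList("d1", [])

    def test_identical_features_tie_broken_by_id(self):
        model = self._model()
        X = np.tile(np.full(11, 0.3), (2, 1))
        pred = score_candidates(model, "d1", ["Db", "Da"], X)
        assert pred.ids() == ["Da", "Db"]

    def test_single_candidate_ranked_first(self):
        model = self._model()
        pred = score_candidates(model, "d1", ["Dx"], np.full((1, 11), -3.0))
        assert pred.ids() == ["Dx"]

    def test_schema_mismatch_rejected(self):
        model = self._model()
        model.schema_hash = "deadbeef"
        with pytest.raises(ValueError, match="schema"):
            score_candidates(model, "d1", ["Da"], np.zeros((1, 11)))

    def test_order_is_descending_by_score(self):
        model = self._model()
        rng = np.random.default_rng(2)
        X = rng.uniform(size=(6, 11))
        pred = score_candidates(model, "d1", [f"D{i}" for i in range(6)], X)
        scores = [it.score for it in pred.items]
        assert scores == sorted(scores, reverse=True)
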