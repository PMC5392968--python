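"""Cost-sensitive classifier: loss, objective, training behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meshrank import (
    Document,
    SvmConfig,
    Vocabulary,
    cost,
    huber_loss,
    predict_score,
    preprocess,
    train_all,
    train_label_model,
)
from meshrank.classification import LabelModel, cost_gradient, doc_features
from meshrank.vocabulary import Descriptor


class TestHuberLoss:
    @pytest.mark.parametrize(
        "z,expected",
        [
            (1.0, 0.0),      # boundary of the zero branch
            (-1.0, 4.0),     # both branches agree at the knot
            (0.0, 1.0),      # (1 − 0)²
            (2.0, 0.0),
            (-2.0, 8.0),
            (0.5, 0.25),
        ],
    )
    def test_piecewise_values(self, z, expected):
        assert huber_loss(z) == pytest.approx(expected)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(min_value=-10, max_value=10))
    def test_continuous_convex_nonnegative(self, z):
        h = huber_loss(z)
        assert h >= 0
        assert (h == 0) == (z >= 1)
        eps = 1e-6
        # continuity
        assert abs(huber_loss(z + eps) - h) < 1e-4
        # midpoint convexity on a symmetric bracket
        assert huber_loss(z) <= 0.5 * (huber_loss(z - 0.5) + huber_loss(z + 0.5)) + 1e-12


def _xy(pairs):
    return [(x, y) for x, y in pairs]


class TestCost:
    def test_zero_model_two_points_matches_hand_value(self):
        model = LabelModel("L")
        data = _xy([({"t": 1.0}, 1), ({"t": 1.0}, -1)])
        cfg = SvmConfig(reg_lambda=0.0)
        # C+·h(0) + C−·h(0) = 1.5·1 + 1.0·1
        assert cost(model, data, cfg) == pytest.approx(2.5)

    def test_separated_data_with_margin_has_zero_cost(self):
        model = LabelModel("L", w={"t": 2.0}, theta=0.0)
        data = _xy([({"t": 1.0}, 1), ({"u": 1.0}, -1)])
        cfg = SvmConfig(reg_lambda=0.0)
        # margins: +1·2 = 2 ≥ 1 and −1·0 = 0 → h(0)=1 for the negative
        assert cost(model, data, cfg) == pytest.approx(1.0)
        model2 = LabelModel("L", w={"t": 2.0}, theta=-1.0)
        assert cost(model2, data, cfg) == pytest.approx(0.0)

    def test_doubling_c_minus_doubles_negative_term_only(self):
        model = LabelModel("L")
        pos = ({"t": 1.0}, 1)
        neg = ({"u": 1.0}, -1)
        cfg1 = SvmConfig(reg_lambda=0.0, c_minus=1.0)
        # halve r so c_plus = r·c_minus stays fixed while c_minus doubles
        cfg2 = SvmConfig(reg_lambda=0.0, c_minus=2.0, cost_ratio_r=0.75)
        pos_term = cost(model, [pos], SvmConfig(reg_lambda=0.0))
        assert cost(model, [pos, neg], cfg2) - cost(model, [pos, neg], cfg1) == (
            pytest.approx(cost(model, [neg], cfg2) - cost(model, [neg], cfg1))
        )
        # r scales the positive term through c_plus = r·c_minus
        assert pos_term == pytest.approx(1.5)

    def test_bad_label_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            cost(LabelModel("L"), [({"t": 1.0}, 0)], SvmConfig())

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        data = []
        for i in range(12):
            x = {f"t{j}": float(rng.normal()) for j in rng.choice(6, size=3, replace=False)}
            data.append((x, 1 if i % 3 == 0 else -1))
        model = LabelModel("L", w={f"t{j}": float(rng.normal()) * 0.3 for j in range(6)},
                           theta=0.1)
        cfg = SvmConfig(reg_lambda=0.05)
        gw, gt = cost_gradient(model, data, cfg)
        eps = 1e-6
        for t in model.w:
            up = LabelModel("L", w={**model.w, t: model.w[t] + eps}, theta=model.theta)
            dn = LabelModel("L", w={**model.w, t: model.w[t] - eps}, theta=model.theta)
            fd = (cost(up, data, cfg) - cost(dn, data, cfg)) / (2 * eps)
            assert gw.get(t, 0.0) == pytest.approx(fd, abs=1e-4)
        up = LabelModel("L", w=model.w, theta=model.theta + eps)
        dn = LabelModel("L", w=model.w, theta=model.theta - eps)
        assert gt == pytest.approx(
            (cost(up, data, cfg) - cost(dn, data, cfg)) / (2 * eps), abs=1e-4
        )


def _toy_docs(n_pos=10, n_neg=10):
    docs = []
    gold = {}
    for i in range(n_pos):
        d = preprocess(Document(f"p{i}", f"marker signal item{i}", ""))
        docs.append(d)
        gold[d.doc_id] = ["L"]
    for i in range(n_neg):
        d = preprocess(Document(f"n{i}", f"background noise item{i}", ""))
        docs.append(d)
        gold[d.doc_id] = []
    return docs, gold


class TestTraining:
    def test_separable_data_reaches_perfect_training_accuracy(self):
        docs, gold = _toy_docs()
        cfg = SvmConfig(reg_lambda=0.0, epochs=30, seed=1)
        model = train_label_model("L", docs, cfg, gold=gold)
        preds = [predict_score(model, d) > 0 for d in docs]
        truth = ["L" in gold[d.doc_id] for d in docs]
        assert preds == truth

    def test_full_batch_cost_non_increasing(self):
        docs, gold = _toy_docs()
        data = [(doc_features(d), 1 if "L" in gold[d.doc_id] else -1) for d in docs]
        cfg = SvmConfig(reg_lambda=0.01, epochs=1, batch_mode="full", seed=0)
        # full-batch descent from a fixed start: more epochs never cost more
        costs = [
            cost(
                train_label_model(
                    "L", docs,
                    SvmConfig(reg_lambda=0.01, epochs=e, batch_mode="full", seed=0),
                    gold=gold,
                ),
                data,
                cfg,
            )
            for e in (1, 2, 4, 8, 16)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(costs, costs[1:]))

    def test_same_seed_reproduces_weights(self):
        docs, gold = _toy_docs()
        cfg = SvmConfig(epochs=5, seed=42)
        m1 = train_label_model("L", docs, cfg, gold=gold)
        m2 = train_label_model("L", docs, cfg, gold=gold)
        assert m1.w == m2.w and m1.theta == m2.theta

    def test_single_class_data_names_label(self):
        docs, gold = _toy_docs(n_pos=0, n_neg=5)
        with pytest.raises(ValueError, match="'L'"):
            train_label_model("L", docs, SvmConfig(), gold=gold)

    def test_higher_cost_ratio_does_not_reduce_positive_recall(self):
        # imbalanced, noisy data: positives share a weak marker token
        rng = np.random.default_rng(7)
        docs, gold = [], {}
        for i in range(15):
            toks = ["marker"] if rng.random() < 0.8 else ["decoy"]
            toks += [f"w{rng.integers(30)}" for _ in range(8)]
            d = preprocess(Document(f"p{i}", " ".join(toks), ""))
            docs.append(d)
            gold[d.doc_id] = ["L"]
        for i in range(150):
            toks = ["marker"] if rng.random() < 0.15 else []
            toks += [f"w{rng.integers(30)}" for _ in range(8)]
            d = preprocess(Document(f"n{i}", " ".join(toks) or "empty", ""))
            docs.append(d)
            gold[d.doc_id] = []
        recalls = []
        for r in (1.0, 1.5, 3.0, 10.0):
            cfg = SvmConfig(reg_lambda=1e-3, cost_ratio_r=r, epochs=20, seed=3)
            model = train_label_model("L", docs, cfg, gold=gold)
            tp = sum(
                predict_score(model, d) > 0 for d in docs if "L" in gold[d.doc_id]
            )
            recalls.append(tp / 15)
        tol = 0.10  # stochastic tolerance on the monotone trend
        assert all(b >= a - tol for a, b in zip(recalls, recalls[1:]))
        assert recalls[-1] >= recalls[0]


class TestTrainAll:
    def _vocab(self):
        v = Vocabulary(
            [Descriptor(f"L{i}", f"label {i}", [], [f"T.{i}"]) for i in range(5)]
        )
        v.set_label_frequencies({"L0": 5, "L1": 4, "L2": 3, "L3": 2, "L4": 1})
        return v

    def _corpus(self):
        docs, gold = [], {}
        rng = np.random.default_rng(0)
        for i in range(20):
            labels = [f"L{j}" for j in range(4) if rng.random() < 0.4]
            text = " ".join(f"sig{lbl}" for lbl in labels) or "plain"
            d = preprocess(Document(f"d{i}", text + f" filler{i % 5}", ""))
            docs.append(d)
            gold[d.doc_id] = labels
        return docs, gold

    def test_unused_label_reported_as_skipped(self):
        docs, gold = self._corpus()
        battery = train_all(docs, gold, self._vocab(), 5, SvmConfig(epochs=3))
        assert "L4" in battery.skipped  # never annotated
        assert set(battery.models) <= {"L0", "L1", "L2", "L3"}
        assert len(battery.models) + len(battery.skipped) == 5

    def test_worker_count_does_not_change_models(self):
        docs, gold = self._corpus()
        cfg = SvmConfig(epochs=3, seed=9)
        b1 = train_all(docs, gold, self._vocab(), 5, cfg, n_jobs=1)
        b2 = train_all(docs, gold, self._vocab(), 5, cfg, n_jobs=4)
        assert b1.models.keys() == b2.models.keys()
        for lbl in b1.models:
            assert b1.models[lbl].w == b2.models[lbl].w

    def test_n_labels_beyond_vocabulary_trains_all_trainable(self):
        docs, gold = self._corpus()
        battery = train_all(docs, gold, self._vocab(), 50, SvmConfig(epochs=3))
        assert len(battery.models) + len(battery.skipped) == 5

    def test_battery_round_trip(self, tmp_path):
        docs, gold = self._corpus()
        battery = train_all(docs, gold, self._vocab(), 5, SvmConfig(epochs=3))
        battery.save(tmp_path / "clf")
        from meshrank.classification import LabelModelBattery

        loaded = LabelModelBattery.load(tmp_path / "clf")
        assert loaded.models.keys() == battery.models.keys()
        for lbl in battery.models:
            assert loaded.models[lbl].w == pytest.approx(battery.models[lbl].w)


class TestPredictScore:
    def test_zero_model_scores_zero(self):
        d = preprocess(Document("x", "anything at all", ""))
        assert predict_score(LabelModel("L"), d) == 0.0

    def test_dot_product_with_threshold(self):
        d = preprocess(Document("x", "marker", ""))
        model = LabelModel("L", w={"marker": 2.0}, theta=-1.0)
        # single token → normalized tf = 1.0
        assert predict_score(model, d) == pytest.approx(1.0)

    def test_disjoint_vocabulary_returns_theta(self):
        d = preprocess(Document("x", "unrelated words", ""))
        model = LabelModel("L", w={"marker": 2.0}, theta=0.25)
        assert predict_score(model, d) == pytest.approx(0.25)
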