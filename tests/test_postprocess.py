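"""Age-tag detection, specificity pruning and the score cutoff."""

import math

import pytest

from meshrank import (
    AgeBracket,
    AgeRule,
    Descriptor,
    Document,
    PredictionList,
    PruningConfig,
    ScoredTerm,
    Vocabulary,
    default_age_rules,
    detect_age_checktags,
    postprocess,
    score_cutoff,
    specificity_prune,
)


def _age_vocab():
    return Vocabulary(
        [
            Descriptor("CT-CHILD", "Child", [], ["M.1"], is_check_tag=True),
            Descriptor("CT-AGED", "Aged", [], ["M.2"], is_check_tag=True),
            Descriptor("CT-ADOL", "Adolescent", [], ["M.3"], is_check_tag=True),
            Descriptor("CT-INF", "Infant", [], ["M.4"], is_check_tag=True),
            Descriptor("D-X", "something else", [], ["X"]),
        ]
    )


class TestAgeDetection:
    def test_child_range_in_years(self):
        rules = default_age_rules(_age_vocab())
        out = detect_age_checktags("we studied children aged 8-10 years", rules)
        assert out == {"CT-CHILD"}

    def test_aged_seventy(self):
        rules = default_age_rules(_age_vocab())
        assert detect_age_checktags("patients aged 70 years", rules) == {"CT-AGED"}

    def test_no_age_keyword_yields_empty(self):
        rules = default_age_rules(_age_vocab())
        assert detect_age_checktags("70 patients with 10 controls", rules) == set()

    def test_months_unit_selects_infant(self):
        rules = default_age_rules(_age_vocab())
        assert detect_age_checktags("infants aged 14 months", rules) == {"CT-INF"}

    def test_range_contributes_both_endpoints(self):
        rules = default_age_rules(_age_vocab())
        out = detect_age_checktags("subjects aged 10 to 15 years", rules)
        assert out == {"CT-CHILD", "CT-ADOL"}

    def test_number_outside_window_ignored(self):
        rules = AgeRule(
            brackets=[AgeBracket(72, 155, "CT-CHILD")], window=10
        )
        text = "aged" + " " * 50 + "9 years"
        assert detect_age_checktags(text, rules) == set()

    def test_first_matching_bracket_wins(self):
        # overlapping nominal ranges resolved by order
        rules = AgeRule(
            brackets=[
                AgeBracket(228, 299, "CT-YA"),
                AgeBracket(228, 539, "CT-ADULT"),
            ]
        )
        assert detect_age_checktags("men aged 20 years", rules) == {"CT-YA"}
        assert detect_age_checktags("men aged 30 years", rules) == {"CT-ADULT"}


def _hier_vocab():
    return Vocabulary(
        [
            Descriptor("DA", "a", [], ["A"]),
            Descriptor("DA1", "a1", [], ["A.1"]),
            Descriptor("DC", "c", [], ["C"]),
        ]
    )


def _pred(pairs, doc_id="d"):
    return PredictionList(doc_id, [ScoredTerm(i, s) for i, s in pairs])


class TestSpecificityPrune:
    def test_parent_below_child_removed(self):
        pred = _pred([("DA1", 3.0), ("DA", 2.0), ("DC", 1.0)])
        out = specificity_prune(pred, _hier_vocab())
        assert out.ids() == ["DA1", "DC"]

    def test_parent_above_child_kept(self):
        pred = _pred([("DA", 3.0), ("DA1", 2.0)])
        out = specificity_prune(pred, _hier_vocab())
        assert out.ids() == ["DA", "DA1"]

    def test_unrelated_terms_unchanged(self):
        pred = _pred([("DC", 3.0), ("DA1", 2.0)])
        assert specificity_prune(pred, _hier_vocab()).ids() == ["DC", "DA1"]

    def test_never_removes_without_higher_ranked_descendant(self):
        # brute-force check over every prediction ordering of the 3 terms
        import itertools

        vocab = _hier_vocab()
        for perm in itertools.permutations(["DA", "DA1", "DC"]):
            pred = _pred([(t, 10.0 - i) for i, t in enumerate(perm)])
            out = specificity_prune(pred, vocab)
            rank = {t: i for i, t in enumerate(perm)}
            for t in perm:
                descendants = vocab.descendants(t)
                should_drop = any(rank[d] < rank[t] for d in descendants
                                  if d in rank)
                assert (t not in out.ids()) == should_drop

    def test_unknown_descriptor_raises(self):
        with pytest.raises(KeyError):
            specificity_prune(_pred([("nope", 1.0)]), _hier_vocab())


class TestScoreCutoff:
    def test_hand_evaluated_cut(self):
        pred = _pred([("D1", 1.0), ("D2", 0.9), ("D3", 0.05)])
        out = score_cutoff(pred, PruningConfig(lambda_cut=0.3))
        # 0.05 < 0.9 · ln 2 · 0.3 ≈ 0.187 → keep the first two
        assert out.ids() == ["D1", "D2"]

    def test_slow_decay_cut_at_cap(self):
        pred = _pred([(f"D{i}", 1.0 - 0.001 * i) for i in range(30)])
        out = score_cutoff(pred, PruningConfig(n_cap=25))
        assert len(out.items) == 25

    def test_single_prediction_kept(self):
        out = score_cutoff(_pred([("D1", 0.2)]), PruningConfig())
        assert out.ids() == ["D1"]

    def test_no_collapse_keeps_everything(self):
        pred = _pred([("D1", 1.0), ("D2", 0.95), ("D3", 0.9)])
        assert len(score_cutoff(pred, PruningConfig()).items) == 3

    def test_output_is_prefix_of_capped_input(self):
        import numpy as np

        rng = np.random.default_rng(0)
        for _ in range(25):
            scores = sorted(rng.uniform(size=int(rng.integers(1, 40))),
                            reverse=True)
            pred = _pred([(f"D{i}", s) for i, s in enumerate(scores)])
            out = score_cutoff(pred, PruningConfig())
            assert out.ids() == pred.ids()[: len(out.items)]
            assert len(out.items) <= 25

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PruningConfig(lambda_cut=0.0)
        with pytest.raises(ValueError):
            PruningConfig(n_cap=2, min_keep=5)


class TestPostprocessPipeline:
    def _vocab(self):
        return Vocabulary(
            [
                Descriptor("CT-CHILD", "Child", [], ["M.1"], is_check_tag=True),
                Descriptor("DA", "a", [], ["A"]),
                Descriptor("DA1", "a1", [], ["A.1"]),
                Descriptor("DC", "c", [], ["C"]),
                Descriptor("DD", "dd", [], ["E"]),
                Descriptor("DE", "ee", [], ["F"]),
            ]
        )

    def test_inert_rules_keep_flat_list(self):
        doc = Document("d", "title", "no ages mentioned here")
        pred = _pred([("DC", 3.0), ("DD", 2.9), ("DE", 2.8)])
        out = postprocess(pred, doc, self._vocab())
        assert out.ids() == ["DC", "DD", "DE"]

    def test_composition_matches_stage_by_stage(self):
        vocab = self._vocab()
        doc = Document("d", "t", "children aged 8 years were enrolled")
        pred = _pred(
            [("DA1", 3.0), ("DA", 2.9), ("DC", 2.8), ("DD", 2.7),
             ("DE", 0.01), ("CT-CHILD", 0.005)][:4]
            + [("DE", 0.01)]
        )
        out = postprocess(pred, doc, vocab)
        # oracle: apply the three stages explicitly
        from meshrank.postprocess import (
            default_age_rules,
            detect_age_checktags,
        )

        rules = default_age_rules(vocab)
        detected = detect_age_checktags(doc.abstract, rules)
        assert detected == {"CT-CHILD"}
        items = [ScoredTerm("CT-CHILD", 3.0 + 1e-6)] + list(pred.items)
        staged = specificity_prune(PredictionList("d", items), vocab)
        expected = score_cutoff(staged, PruningConfig())
        assert out.ids() == expected.ids()
        assert "CT-CHILD" in out.ids()
        assert "DA" not in out.ids()  # out-ranked parent of DA1

    def test_idempotence(self):
        vocab = self._vocab()
        doc = Document("d", "t", "children aged 8 years were enrolled")
        pred = _pred([("DA1", 3.0), ("DA", 2.9), ("DC", 2.8), ("DE", 0.01)])
        once = postprocess(pred, doc, vocab)
        twice = postprocess(once, doc, vocab)
        assert [it.descriptor_id for it in twice.items] == once.ids()
        assert [it.score for it in twice.items] == [
            it.score for it in once.items
        ]

    def test_detected_tag_already_present_not_duplicated(self):
        vocab = self._vocab()
        doc = Document("d", "t", "children aged 8 years")
        pred = _pred([("CT-CHILD", 3.0), ("DC", 2.0)])
        out = postprocess(pred, doc, vocab)
        assert out.ids().count("CT-CHILD") == 1
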