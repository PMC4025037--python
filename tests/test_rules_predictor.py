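from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vspredict.core_events import ComplexEventSequence, SimultaneousEventSet
from vspredict.episode_mining import Episode, EpisodeStats, mine_frequent_episodes
from vspredict.rules_predictor import (
    EpisodeRule,
    GuidelineMap,
    Prediction,
    RuleBase,
    evaluate,
    generate_rules,
    match_predict,
    recommend,
)

E = Episode.of


def buffer_of(*event_sets: str) -> ComplexEventSequence:
    return ComplexEventSequence(
        [
            SimultaneousEventSet(i + 1, frozenset(ev.split()))
            for i, ev in enumerate(event_sets)
        ],
        tick_width=1.0,
    )


class TestGenerateRules:
    def test_confidence_from_worked_example_counts(self, fig4_window1, example_params):
        stats = mine_frequent_episodes(fig4_window1, example_params)
        rules = generate_rules(stats, min_support=2, min_confidence=0.0)
        bb = next(r for r in rules if r.antecedent == E("B") and r.consequent == E("B"))
        assert bb.confidence == pytest.approx(3 / 4)  # support(BB)=3 over support(B)=4
        assert bb.support == 3
        cb = next(r for r in rules if r.antecedent == E("C") and r.consequent == E("B"))
        assert cb.confidence == pytest.approx(1.0)  # support(CB)=3 over support(C)=3

    def test_length_one_episodes_yield_no_rules(self):
        stats = {E("A"): EpisodeStats(E("A"), [(1, 1), (2, 2)])}
        assert len(generate_rules(stats, 1, 0.0)) == 0

    def test_multi_step_antecedent_splits_produced(self, fig4_window1, example_params):
        stats = mine_frequent_episodes(fig4_window1, example_params)
        splits = {
            (r.antecedent, r.consequent)
            for r in generate_rules(stats, 2, 0.0)
            if r.full_episode == E("B", "B", "B")
        }
        assert splits == {(E("B"), E("B", "B")), (E("B", "B"), E("B"))}

    def test_confidence_never_exceeds_one(self, fig4_window1, example_params):
        stats = mine_frequent_episodes(fig4_window1, example_params)
        assert all(0 < r.confidence <= 1 for r in generate_rules(stats, 2, 0.0))

    def test_ordering_is_total_and_deterministic(self, fig4_window1, example_params):
        stats = mine_frequent_episodes(fig4_window1, example_params)
        a = generate_rules(stats, 2, 0.0)
        b = generate_rules(dict(reversed(list(stats.items()))), 2, 0.0)
        assert a.rules == b.rules
        keys = [(-r.confidence, -r.support, r.antecedent.key, r.consequent.key) for r in a]
        assert keys == sorted(keys)

    def test_min_confidence_threshold_applies(self, fig4_window1, example_params):
        stats = mine_frequent_episodes(fig4_window1, example_params)
        assert all(r.confidence >= 0.8 for r in generate_rules(stats, 2, 0.8))

    def test_invalid_min_confidence_rejected(self):
        with pytest.raises(ValueError, match="min_confidence"):
            generate_rules({}, 1, 1.5)

    def test_rules_json_round_trip(self, tmp_path, fig4_window1, example_params):
        stats = mine_frequent_episodes(fig4_window1, example_params)
        rules = generate_rules(stats, 2, 0.5)
        path = tmp_path / "rules.json"
        rules.to_json(path)
        again = RuleBase.from_json(path)
        assert again.rules == rules.rules
        assert (again.min_support, again.min_confidence) == (2, 0.5)


class TestMatchPredict:
    def tachycardia_rules(self) -> RuleBase:
        return RuleBase(
            [
                EpisodeRule(E("Pulse_H"), E("BP_HB"), support=5, confidence=0.9),
                EpisodeRule(E("Pulse_L"), E("BP_H1"), support=4, confidence=0.8),
            ],
            min_support=2,
            min_confidence=0.5,
        )

    def test_rule_fires_on_anchored_antecedent(self):
        prediction = match_predict(self.tachycardia_rules(), buffer_of("Pulse_H"), 4)
        assert prediction.predicted_states == frozenset({"BP_HB"})
        assert prediction.matched_rule.antecedent == E("Pulse_H")
        assert prediction.horizon == 1

    def test_antecedent_must_end_at_latest_tick(self):
        # tachycardia two ticks ago, normal-ish now: nothing anchors
        prediction = match_predict(
            self.tachycardia_rules(), buffer_of("Pulse_H", "SpO2_Lmicro"), 4
        )
        assert prediction.is_empty

    def test_empty_rule_base_predicts_nothing(self):
        prediction = match_predict(RuleBase([], 2, 0.5), buffer_of("Pulse_H"), 4)
        assert prediction.is_empty and prediction.predicted_states == frozenset()

    def test_equal_confidence_breaks_tie_by_support(self):
        low = EpisodeRule(E("X"), E("L"), support=2, confidence=0.9)
        high = EpisodeRule(E("X"), E("W"), support=7, confidence=0.9)
        for order in ([low, high], [high, low]):
            rules = generate_rules_like(order)
            prediction = match_predict(rules, buffer_of("X"), 4)
            assert prediction.predicted_states == frozenset({"W"})

    def test_multi_step_antecedent_spans_buffer(self):
        rule = EpisodeRule(E("Pulse_H", "Pulse_H"), E("BP_HB"), 3, 0.8)
        rules = RuleBase([rule], 2, 0.5)
        hit = match_predict(rules, buffer_of("Pulse_H", "N", "Pulse_H"), 4)
        assert hit.predicted_states == frozenset({"BP_HB"})
        # span must fit the window
        miss = match_predict(rules, buffer_of("Pulse_H", "N", "N", "N", "Pulse_H"), 4)
        assert miss.is_empty

    def test_prediction_invariant(self):
        with pytest.raises(ValueError):
            Prediction(frozenset({"BP_HB"}), None)


def generate_rules_like(rules: list[EpisodeRule]) -> RuleBase:
    """Order a hand-built rule list exactly as the generator would."""
    ordered = sorted(
        rules,
        key=lambda r: (-r.confidence, -r.support, r.antecedent.key, r.consequent.key),
    )
    return RuleBase(ordered, min_support=1, min_confidence=0.0)


class TestRecommend:
    def make_prediction(self, *labels: str) -> Prediction:
        return Prediction(
            frozenset(labels),
            EpisodeRule(E("Pulse_H"), E(tuple(labels)), 3, 0.9),
        )

    def test_exact_pattern_lookup(self):
        gm = GuidelineMap()
        gm.add({"BP_HB"}, "recheck blood pressure in 15 minutes")
        rec = recommend(self.make_prediction("BP_HB"), gm)
        assert rec.guidelines[0][1].startswith("recheck")
        assert not rec.state_only

    def test_missing_guideline_reports_state_only(self):
        rec = recommend(self.make_prediction("BP_H2"), GuidelineMap())
        assert rec.state_only and rec.states == frozenset({"BP_H2"})
        assert rec.guidelines == ()

    def test_per_label_fallback_for_combined_states(self):
        gm = GuidelineMap()
        gm.add({"Pulse_H"}, "assess for fever or pain")
        gm.add({"BP_HB"}, "recheck blood pressure")
        rec = recommend(self.make_prediction("Pulse_H", "BP_HB"), gm)
        assert len(rec.guidelines) == 2 and not rec.state_only

    def test_exact_match_beats_fallback(self):
        gm = GuidelineMap()
        gm.add({"Pulse_H"}, "single")
        gm.add({"Pulse_H", "BP_HB"}, "combined tachycardia with prehypertension")
        rec = recommend(self.make_prediction("Pulse_H", "BP_HB"), gm)
        assert [text for _, text in rec.guidelines] == [
            "combined tachycardia with prehypertension"
        ]

    def test_empty_prediction_yields_no_recommendation(self):
        assert recommend(Prediction(frozenset(), None), GuidelineMap()) is None

    def test_guideline_file_formats(self, tmp_path):
        j = tmp_path / "g.json"
        j.write_text('{"BP_HB": "recheck", "Pulse_H+BP_HB": "combined"}')
        gm = GuidelineMap.load(j)
        assert gm.entries[frozenset({"Pulse_H", "BP_HB"})][1] == "combined"
        t = tmp_path / "g.tsv"
        t.write_text("# comment\nBP_HB\trecheck\nPulse_H+BP_HB\tcombined\n")
        gm2 = GuidelineMap.load(t)
        assert gm2.entries.keys() == gm.entries.keys()

    def test_duplicate_patterns_rejected(self):
        gm = GuidelineMap()
        gm.add({"BP_HB"}, "a")
        with pytest.raises(ValueError, match="duplicate"):
            gm.add({"BP_HB"}, "b")


class TestEvaluate:
    def test_perfect_prediction(self):
        truth = [{"BP_HB"}, {"Pulse_H"}, {"BP_HB"}]
        report = evaluate(truth, truth)
        assert (report.precision, report.recall, report.f_measure) == (1.0, 1.0, 1.0)
        assert report.m == 2

    def test_hand_computed_confusion(self):
        report = evaluate(predicted=["X", "Y", "Y"], truth=["X", "X", "Y"])
        assert report.precision == pytest.approx(0.75)
        assert report.recall == pytest.approx(0.75)
        assert report.f_measure == pytest.approx(0.75)
        assert report.per_class[("X",)] == {"tp": 1, "fp": 0, "fn": 1}
        assert report.per_class[("Y",)] == {"tp": 1, "fp": 1, "fn": 0}

    def test_single_category_all_predicted(self):
        report = evaluate(["X", "X"], ["X", "X"])
        assert report.precision == report.recall == 1.0 and report.m == 1

    def test_state_sets_are_categories_regardless_of_order(self):
        report = evaluate([{"Pulse_H", "BP_HB"}], [{"BP_HB", "Pulse_H"}])
        assert report.f_measure == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            evaluate(["X"], ["X", "Y"])

    @given(st.permutations(range(8)))
    @settings(max_examples=50, derandomize=True)
    def test_permutation_equivariance(self, perm):
        pred = ["X", "Y", "X", "Z", "Y", "Y", "X", "Z"]
        truth = ["X", "X", "Y", "Z", "Y", "Z", "X", "X"]
        base = evaluate(pred, truth)
        shuffled = evaluate([pred[i] for i in perm], [truth[i] for i in perm])
        assert shuffled.precision == pytest.approx(base.precision)
        assert shuffled.recall == pytest.approx(base.recall)
        assert shuffled.f_measure == pytest.approx(base.f_measure)

    @pytest.mark.parametrize("average", ["macro", "micro"])
    def test_cross_check_against_sklearn(self, average):
        from sklearn.metrics import precision_score, recall_score

        rng = np.random.default_rng(11)
        labels = ["X", "Y", "Z"]
        pred = rng.choice(labels, size=60).tolist()
        truth = rng.choice(labels, size=60).tolist()
        report = evaluate(pred, truth, average=average)
        assert report.precision == pytest.approx(
            precision_score(truth, pred, average=average, zero_division=0)
        )
        assert report.recall == pytest.approx(
            recall_score(truth, pred, average=average, zero_division=0)
        )
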