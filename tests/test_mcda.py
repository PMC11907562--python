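"""Weight allocation, partial value functions, scoring and ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petrushka.combine import PredictionSet
from petrushka.errors import (
    DegenerateInputError,
    EmptyCandidateError,
    InvalidArgumentError,
)
from petrushka.mcda import (
    PreferenceInput,
    WeightScheme,
    allocate_weights,
    partial_value,
    recommend,
    recommend_top3,
    score_drugs,
)

AES = ["nausea", "insomnia", "headache", "dizziness"]


def _pred(drug_outcomes, aes=()):
    """drug -> (hdrs, p_drop, {ae: p})"""
    return PredictionSet(
        patient_id="p1",
        drugs={d: {"expected_hdrs_8wk": h, "p_discontinue": p,
                   "p_ae": dict(ae)} for d, (h, p, ae) in drug_outcomes.items()})


class TestAllocateWeights:
    def test_equal_split_over_three_selected(self):
        w = allocate_weights(PreferenceInput(selected_aes=AES[:3]), AES)
        assert all(v == pytest.approx(0.333, abs=1e-3) for v in
                   (w.w_efficacy, w.w_acceptability, w.w_side_effects))
        assert all(v == pytest.approx(1 / 9) for v in w.ae_weights.values())

    def test_opt_out_spreads_over_all_modeled_events(self):
        w = allocate_weights(PreferenceInput(elicit_opt_out=True), AES)
        assert set(w.ae_weights) == set(AES)
        assert all(v == pytest.approx(1 / 3 / 4) for v in w.ae_weights.values())

    def test_inverse_rank_weighting(self):
        w = allocate_weights(PreferenceInput(selected_aes=AES[:2], ranks=[1, 2]), AES)
        assert w.ae_weights[AES[0]] == pytest.approx(2 / 9)   # 0.222
        assert w.ae_weights[AES[1]] == pytest.approx(1 / 9)   # 0.111

    def test_unknown_selected_event_rejected(self):
        with pytest.raises(InvalidArgumentError):
            allocate_weights(PreferenceInput(selected_aes=["vertigo"]), AES)

    def test_more_than_five_selections_rejected(self):
        with pytest.raises(Exception):
            PreferenceInput(selected_aes=AES + ["dry_mouth", "tremor"])

    def test_bad_rank_permutation_rejected(self):
        with pytest.raises(Exception):
            PreferenceInput(selected_aes=AES[:2], ranks=[1, 3])

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 4), st.booleans())
    def test_weights_always_sum_to_one(self, n_sel, opt_out):
        prefs = PreferenceInput(selected_aes=AES[:n_sel], elicit_opt_out=opt_out)
        w = allocate_weights(prefs, AES)
        assert w.total == pytest.approx(1.0)


class TestPartialValue:
    def test_anchors_and_midpoint(self):
        assert partial_value(10.0, worst=10.0, best=0.0) == 0.0
        assert partial_value(0.0, worst=10.0, best=0.0) == 1.0
        assert partial_value(5.0, worst=10.0, best=0.0) == 0.5

    def test_clamped_outside_anchor_range(self):
        assert partial_value(12.0, worst=10.0, best=0.0) == 0.0
        assert partial_value(-1.0, worst=10.0, best=0.0) == 1.0

    def test_degenerate_anchors_rejected(self):
        with pytest.raises(DegenerateInputError):
            partial_value(1.0, worst=2.0, best=2.0)


class TestScoring:
    def test_dominant_drug_scores_one_dominated_zero(self):
        pred = _pred({"a": (10.0, 0.1, {"nausea": 0.05}),
                      "b": (20.0, 0.3, {"nausea": 0.25}),
                      "c": (15.0, 0.2, {"nausea": 0.10})})
        w = allocate_weights(PreferenceInput(selected_aes=["nausea"]), ["nausea"])
        s = score_drugs(pred, w)
        assert s["a"] == pytest.approx(1.0)
        assert s["b"] == pytest.approx(0.0)
        assert 0.0 < s["c"] < 1.0

    def test_two_outcome_trade_off_averages(self):
        pred = _pred({"a": (10.0, 0.4, {}), "b": (20.0, 0.1, {})})
        w = WeightScheme(w_efficacy=0.5, w_acceptability=0.5, w_side_effects=0.0)
        s = score_drugs(pred, w)
        assert s["a"] == pytest.approx(0.5)
        assert s["b"] == pytest.approx(0.5)

    def test_zero_side_effect_weight_ignores_ae_probabilities(self):
        base = {"a": (10.0, 0.1, {"nausea": 0.9}), "b": (15.0, 0.2, {"nausea": 0.0})}
        alt = {"a": (10.0, 0.1, {"nausea": 0.0}), "b": (15.0, 0.2, {"nausea": 0.9})}
        w = WeightScheme(w_efficacy=0.5, w_acceptability=0.5, w_side_effects=0.0,
                         ae_weights={"nausea": 1.0})
        assert score_drugs(_pred(base), w) == score_drugs(_pred(alt), w)

    def test_weak_dominance_never_ranked_below(self):
        pred = _pred({"a": (12.0, 0.15, {"nausea": 0.1}),
                      "b": (12.0, 0.15, {"nausea": 0.2}),   # dominated by a
                      "c": (11.0, 0.25, {"nausea": 0.15})})
        w = allocate_weights(PreferenceInput(selected_aes=["nausea"]), ["nausea"])
        s = score_drugs(pred, w)
        assert s["a"] >= s["b"]

    def test_global_anchors_mode(self):
        pred = _pred({"a": (0.0, 0.1, {}), "b": (52.0, 0.1, {})})
        w = WeightScheme(w_efficacy=1.0, w_acceptability=0.0, w_side_effects=0.0)
        s = score_drugs(pred, w, anchors="global")
        assert s["a"] == pytest.approx(1.0)
        assert s["b"] == pytest.approx(0.0)


class TestRecommend:
    PRED = {"a": (10.0, 0.10, {"nausea": 0.05}),
            "b": (12.0, 0.15, {"nausea": 0.10}),
            "c": (14.0, 0.20, {"nausea": 0.15}),
            "d": (16.0, 0.25, {"nausea": 0.20})}

    def test_top3_are_three_best_with_dots(self):
        rec = recommend(_pred(self.PRED), PreferenceInput(selected_aes=["nausea"]))
        assert rec.top3 == ["a", "b", "c"]
        assert rec.dot_strength["a"] == 5
        assert rec.dot_strength["d"] == 1
        assert all(0.0 <= v <= 1.0 for v in rec.values.values())

    def test_excluded_drug_absent_even_if_best(self):
        rec = recommend(_pred(self.PRED),
                        PreferenceInput(selected_aes=["nausea"],
                                        clinician_exclusions=["a"]))
        assert "a" not in rec.values
        assert rec.top3 == ["b", "c", "d"]
        assert rec.excluded == ["a"]

    def test_exclusion_applied_before_anchor_computation(self):
        # with "a" excluded, "b" becomes the best candidate and must score 1
        rec = recommend(_pred(self.PRED),
                        PreferenceInput(selected_aes=["nausea"],
                                        clinician_exclusions=["a"]))
        assert rec.values["b"] == pytest.approx(1.0)

    def test_all_excluded_raises(self):
        with pytest.raises(EmptyCandidateError):
            recommend(_pred(self.PRED),
                      PreferenceInput(clinician_exclusions=list("abcd")))

    def test_breakdown_restricted_to_selected_events(self):
        pred = _pred({d: (h, p, {"nausea": 0.1, "insomnia": 0.2})
                      for d, (h, p, _) in self.PRED.items()})
        rec = recommend(pred, PreferenceInput(selected_aes=["insomnia"]))
        for d in rec.top3:
            assert set(rec.ae_breakdown[d]) == {"insomnia"}

    def test_tie_break_prefers_better_efficacy(self):
        pred = _pred({"x": (10.0, 0.2, {}), "y": (12.0, 0.1, {})})
        scores = {"x": 0.5, "y": 0.5}
        rec = recommend_top3(scores, PreferenceInput(), pred)
        assert rec.ranking == ["x", "y"]

    def test_ranking_invariant_to_name_relabeling(self):
        rec1 = recommend(_pred(self.PRED), PreferenceInput())
        relabeled = {d.upper(): v for d, v in self.PRED.items()}
        rec2 = recommend(_pred(relabeled), PreferenceInput())
        assert [d.upper() for d in rec1.ranking] == rec2.ranking
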