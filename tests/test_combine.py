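"""Combiner algebra and full per-patient profile assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petrushka.combine import combine_binary, combine_continuous, predict_profile
from petrushka.errors import BoundaryError, ConfigurationError, InvalidArgumentError
from petrushka.nma import ModifierModel, RelativeEffects


class TestContinuous:
    def test_reference_identity_and_addition(self):
        assert combine_continuous(15.0, 0.0) == 15.0
        assert combine_continuous(15.0, -2.0) == 13.0

    def test_clamped_to_scale(self):
        assert combine_continuous(1.0, -3.0) == 0.0
        assert combine_continuous(50.0, 5.0) == 52.0

    def test_non_finite_rejected(self):
        with pytest.raises(InvalidArgumentError):
            combine_continuous(np.nan, 0.0)


class TestBinary:
    def test_identity_odds_ratio(self):
        assert combine_binary(0.5, 1.0) == pytest.approx(0.5, abs=1e-12)

    def test_hand_worked_odds_arithmetic(self):
        # odds 0.25 * 2 = 0.5 -> p = 1/3
        assert combine_binary(0.2, 2.0) == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_inverse_property(self):
        for p, orr in [(0.3, 0.5), (0.77, 4.2), (0.01, 12.0)]:
            assert combine_binary(combine_binary(p, orr), 1 / orr) == pytest.approx(
                p, abs=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(0.001, 0.999), st.floats(0.01, 100), st.floats(0.01, 100))
    def test_odds_ratio_composition(self, p, or1, or2):
        chained = combine_binary(combine_binary(p, or1), or2)
        assert combine_binary(p, or1 * or2) == pytest.approx(chained, abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.98), st.floats(0.1, 10))
    def test_monotone_in_both_arguments(self, p, dp, orr):
        q = min(p + dp, 0.995)
        assert combine_binary(q, orr) >= combine_binary(p, orr)
        assert combine_binary(p, orr * 1.5) >= combine_binary(p, orr)

    def test_boundary_probability_rejected(self):
        with pytest.raises(BoundaryError):
            combine_binary(0.0, 2.0)
        with pytest.raises(BoundaryError):
            combine_binary(1.0, 2.0)
        with pytest.raises(InvalidArgumentError):
            combine_binary(0.5, -1.0)


class _ConstantModel:
    """Stub absolute model emitting a fixed value."""

    def __init__(self, value, family):
        self.value, self.family = value, family

    def predict(self, X, clip=True):
        return np.array([self.value])


def _toy_components(deltas, drop_ors, ae_ors=None, p_drop=0.3, hdrs_ref=15.0):
    drugs = sorted(deltas)
    non_ref = [d for d in drugs if d != "fluoxetine"]
    cov = pd.DataFrame(np.zeros((len(non_ref), len(non_ref))),
                       index=[f"trt_{d}" for d in non_ref],
                       columns=[f"trt_{d}" for d in non_ref])
    modifier = ModifierModel(reference="fluoxetine", treatments=non_ref,
                             main_effects={d: deltas[d] for d in non_ref},
                             interactions={}, centres={}, tau2=0.0, cov_params=cov)
    drop_re = RelativeEffects(reference="fluoxetine", tau2=0.0, scale="log_odds_ratio",
                              effects={d: (np.log(drop_ors[d]) if d != "fluoxetine" else 0.0,
                                           0.0) for d in drugs})
    abs_models = {"efficacy": _ConstantModel(hdrs_ref, "continuous"),
                  "discontinuation": _ConstantModel(p_drop, "binary")}
    rel = {"efficacy": modifier, "discontinuation": drop_re}
    if ae_ors:
        abs_models["ae"] = {ae: _ConstantModel(0.2, "binary") for ae in ae_ors}
        rel["ae"] = {ae: RelativeEffects(
            reference="paroxetine", tau2=0.0, scale="log_odds_ratio",
            effects={d: (np.log(ors[d]) if d != "paroxetine" else 0.0, 0.0)
                     for d in drugs}) for ae, ors in ae_ors.items()}
    else:
        abs_models["ae"], rel["ae"] = {}, {}
    return abs_models, rel


class TestPredictProfile:
    PATIENT = {"age": 45.0, "hdrs_total": 24.0}

    def test_reference_passthrough(self):
        am, rel = _toy_components({"fluoxetine": 0.0, "sertraline": -2.0},
                                  {"fluoxetine": 1.0, "sertraline": 0.5})
        pred = predict_profile(self.PATIENT, am, rel,
                               ["fluoxetine", "sertraline"], feature_row=np.zeros((1, 1)))
        assert pred.expected_hdrs("fluoxetine") == 15.0
        assert pred.p_discontinue("fluoxetine") == pytest.approx(0.3)

    def test_null_network_makes_all_drugs_identical(self):
        am, rel = _toy_components({"fluoxetine": 0.0, "sertraline": 0.0,
                                   "citalopram": 0.0},
                                  {"fluoxetine": 1.0, "sertraline": 1.0,
                                   "citalopram": 1.0})
        pred = predict_profile(self.PATIENT, am, rel,
                               ["fluoxetine", "sertraline", "citalopram"],
                               feature_row=np.zeros((1, 1)))
        vals = {(pred.expected_hdrs(d), round(pred.p_discontinue(d), 12))
                for d in pred.drugs}
        assert len(vals) == 1

    def test_hand_worked_discontinuation_probability(self):
        am, rel = _toy_components({"fluoxetine": 0.0, "sertraline": -2.0},
                                  {"fluoxetine": 1.0, "sertraline": 0.5})
        pred = predict_profile(self.PATIENT, am, rel,
                               ["fluoxetine", "sertraline"], feature_row=np.zeros((1, 1)))
        # odds 3/7 * 0.5 -> p = 0.1765
        assert pred.p_discontinue("sertraline") == pytest.approx(3 / 7 * 0.5 / (1 + 3 / 7 * 0.5),
                                                                 abs=1e-10)
        assert pred.expected_hdrs("sertraline") == pytest.approx(13.0)

    def test_adverse_events_use_paroxetine_reference(self):
        am, rel = _toy_components(
            {"fluoxetine": 0.0, "paroxetine": -0.5},
            {"fluoxetine": 1.0, "paroxetine": 1.2},
            ae_ors={"nausea": {"fluoxetine": 0.8, "paroxetine": 1.0}})
        pred = predict_profile(self.PATIENT, am, rel, ["fluoxetine", "paroxetine"],
                               feature_row=np.zeros((1, 1)))
        assert pred.p_ae("paroxetine", "nausea") == pytest.approx(0.2)
        assert pred.p_ae("fluoxetine", "nausea") == pytest.approx(
            combine_binary(0.2, 0.8), abs=1e-12)

    def test_missing_drug_names_offending_component(self):
        am, rel = _toy_components({"fluoxetine": 0.0, "sertraline": -2.0},
                                  {"fluoxetine": 1.0, "sertraline": 0.5})
        with pytest.raises(ConfigurationError, match="efficacy"):
            predict_profile(self.PATIENT, am, rel, ["fluoxetine", "venlafaxine"],
                            feature_row=np.zeros((1, 1)))

    def test_long_format_export(self):
        am, rel = _toy_components({"fluoxetine": 0.0, "sertraline": -2.0},
                                  {"fluoxetine": 1.0, "sertraline": 0.5})
        pred = predict_profile(self.PATIENT, am, rel, ["fluoxetine", "sertraline"],
                               feature_row=np.zeros((1, 1)))
        df = pred.to_long_frame()
        assert set(df.columns) == {"patient", "drug", "outcome", "value"}
        assert len(df) == 4  # 2 drugs x (hdrs, p_discontinue)
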