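"""Pairwise pooling, aggregate-network NMA, and the one-stage IPD model."""

import numpy as np
import pandas as pd
import pytest

from petrushka.errors import (
    IdentifiabilityError,
    InvalidArgumentError,
    NetworkError,
)
from petrushka.nma import ModifierModel, fit_ad_nma, fit_ipd_nma, pairwise_ma
from petrushka.synthetic import default_truth, generate_ad_network, generate_rct_ipd
from petrushka.treatments import TREATMENTS


class TestPairwise:
    def test_single_study_identity(self):
        r = pairwise_ma([(1.0, 0.5)])
        assert (r.pooled, r.se, r.tau2) == (1.0, 0.5, 0.0)

    def test_hand_worked_dersimonian_laird(self):
        # w={1,1}: Q=2, df=1, C=2-1=1 -> tau2=1; re-pooled se=1
        r = pairwise_ma([(1.0, 1.0), (3.0, 1.0)])
        assert r.pooled == pytest.approx(2.0)
        assert r.q == pytest.approx(2.0)
        assert r.tau2 == pytest.approx(1.0)
        assert r.se == pytest.approx(1.0)

    def test_homogeneous_studies_have_zero_tau2(self):
        r = pairwise_ma([(0.8, 0.3)] * 6)
        assert r.pooled == pytest.approx(0.8)
        assert r.tau2 == 0.0

    def test_empty_and_invalid_inputs_rejected(self):
        with pytest.raises(InvalidArgumentError):
            pairwise_ma([])
        with pytest.raises(InvalidArgumentError):
            pairwise_ma([(1.0, 0.0)])


def _two_arm_log_ors(net: pd.DataFrame):
    """Independent oracle: per-study log ORs with the same continuity rule."""
    out = []
    for _, g in net.groupby("study_id"):
        g = g.reset_index(drop=True)
        e = g["events"].to_numpy(float)
        n = g["n"].to_numpy(float)
        if (e == 0).all() or (e == n).all():
            continue
        if ((e == 0) | (e == n)).any():
            e, n = e + 0.5, n + 1.0
        lo = np.log(e / (n - e))
        var = 1 / e + 1 / (n - e)
        out.append((lo[1] - lo[0], np.sqrt(var[0] + var[1])))
    return out


class TestAggregateNMA:
    def test_two_treatment_network_equals_pairwise(self, truth):
        net = generate_ad_network(per_arm_n=150, truth=truth, seed=1,
                                  design=[("fluoxetine", "sertraline")] * 6)
        res = fit_ad_nma(net, "fluoxetine")
        oracle = pairwise_ma(_two_arm_log_ors(net))
        assert res.effects["sertraline"][0] == pytest.approx(oracle.pooled, abs=1e-8)
        assert res.effects["sertraline"][1] == pytest.approx(oracle.se, abs=1e-8)
        assert res.tau2 == pytest.approx(oracle.tau2, abs=1e-8)

    def test_reference_relabeling_leaves_contrasts_unchanged(self, truth):
        net = generate_ad_network(12, 200, truth, seed=2)
        a = fit_ad_nma(net, "fluoxetine")
        b = fit_ad_nma(net, "sertraline")
        drugs = sorted(set(net["treatment"]) - {"fluoxetine", "sertraline"})
        for d in drugs[:6]:
            assert a.contrast(d, "sertraline") == pytest.approx(
                b.contrast(d, "sertraline"), abs=1e-10)

    def test_consistent_triangle_is_additive(self):
        t = default_truth(tau2=0.0)
        design = [("fluoxetine", "sertraline"), ("sertraline", "paroxetine"),
                  ("fluoxetine", "paroxetine")] * 4
        net = generate_ad_network(per_arm_n=4000, truth=t, seed=3, design=design)
        res = fit_ad_nma(net, "fluoxetine")
        direct = res.contrast("sertraline", "paroxetine")
        indirect = res.estimate("sertraline") - res.estimate("paroxetine")
        assert direct == pytest.approx(indirect, abs=1e-10)  # same basic params
        true_diff = (t.log_ors_dropout["sertraline"] - t.log_ors_dropout["paroxetine"])
        assert direct == pytest.approx(true_diff, abs=0.15)  # Monte-Carlo tolerance

    def test_disconnected_network_lists_components(self, truth):
        a = generate_ad_network(per_arm_n=50, truth=truth, seed=4,
                                design=[("fluoxetine", "sertraline")])
        b = generate_ad_network(per_arm_n=50, truth=truth, seed=5,
                                design=[("mirtazapine", "venlafaxine")])
        b["study_id"] = "study_other"
        net = pd.concat([a, b], ignore_index=True)
        with pytest.raises(NetworkError) as err:
            fit_ad_nma(net, "fluoxetine")
        assert len(err.value.components) == 2

    def test_zero_event_arm_handled_by_continuity_correction(self):
        net = pd.DataFrame({
            "study_id": ["s1", "s1", "s2", "s2"],
            "treatment": ["fluoxetine", "sertraline"] * 2,
            "n": [50, 50, 80, 80],
            "events": [0, 5, 10, 12],
        })
        res = fit_ad_nma(net, "fluoxetine")
        assert np.isfinite(res.effects["sertraline"][0])

    def test_reference_entry_is_exact_zero(self, truth):
        net = generate_ad_network(10, 100, truth, seed=5)
        res = fit_ad_nma(net, "fluoxetine")
        assert res.effects["fluoxetine"] == (0.0, 0.0)


class TestIPDNMA:
    def test_reference_and_centre_identities(self, ipd_small):
        m = fit_ipd_nma(ipd_small, "fluoxetine", modifiers=("hdrs_total", "age"))
        assert m.predict_delta({"hdrs_total": 0, "age": 0}, "fluoxetine") == (0.0, 0.0)
        centre = {"hdrs_total": m.centres["hdrs_total"], "age": m.centres["age"]}
        d, se = m.predict_delta(centre, "sertraline")
        assert d == pytest.approx(m.main_effects["sertraline"], abs=1e-10)
        assert se > 0

    def test_zero_interaction_truth_recovers_null_interactions(self):
        t = default_truth(tau2=0.0, modifier_coefficients={})
        ipd = generate_rct_ipd(16, 300, truth=t, seed=6)
        m = fit_ipd_nma(ipd, "fluoxetine", modifiers=("hdrs_total", "age"))
        # z-scores of the interaction estimates should be unremarkable
        for cov in ("hdrs_total", "age"):
            se = np.sqrt(m.cov_params.loc[f"int_{cov}", f"int_{cov}"])
            assert abs(m.interactions[cov]) < 4 * se

    def test_unknown_drug_rejected(self, ipd_small):
        m = fit_ipd_nma(ipd_small, "fluoxetine")
        with pytest.raises(InvalidArgumentError):
            m.predict_delta({"hdrs_total": 20, "age": 40}, "ketamine")

    def test_constant_modifier_raises_identifiability_error(self, ipd_small):
        bad = ipd_small.copy()
        bad["flat"] = 1.0
        with pytest.raises(IdentifiabilityError):
            fit_ipd_nma(bad, "fluoxetine", modifiers=("flat",))

    def test_hand_built_model_linear_predictor(self):
        cov = pd.DataFrame(np.zeros((2, 2)),
                           index=["trt_sertraline", "int_age"],
                           columns=["trt_sertraline", "int_age"])
        m = ModifierModel(reference="fluoxetine", treatments=["sertraline"],
                          main_effects={"sertraline": -2.0},
                          interactions={"age": 0.5}, centres={"age": 45.0},
                          tau2=0.0, cov_params=cov)
        d, se = m.predict_delta({"age": 47}, "sertraline")
        assert d == pytest.approx(-2.0 + 0.5 * 2)  # = -1.0
        assert se == 0.0

    def test_json_round_trip_fields(self, ipd_small, tmp_path):
        m = fit_ipd_nma(ipd_small, "fluoxetine")
        import json

        payload = json.loads(m.to_json(tmp_path / "m.json"))
        assert payload["reference"] == "fluoxetine"
        assert set(payload["main_effects"]) == set(m.treatments)
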