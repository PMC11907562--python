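"""Fuse absolute reference-drug predictions with relative effects.

The engine never fits an outcome model per drug. It predicts the absolute
outcome on the *reference* drug (from the EHR-based models) and maps it onto
every other drug with network-meta-analytic relative effects:

* continuous severity — additive on the HDRS scale:
  ``HDRS(drug) = HDRS(reference) + delta(drug vs reference)``, clamped to
  the 0-52 scale;
* binary events — multiplicative on the odds scale:
  ``odds(drug) = odds(reference) * OR(drug vs reference)``.

:func:`predict_profile` assembles the full per-patient prediction set across
drugs and outcomes: efficacy (reference fluoxetine, patient-specific deltas
from the IPD-NMA modifier model, PHQ-9 predictions converted to HDRS first),
all-cause discontinuation (fluoxetine-referenced odds ratios), and each
screened-in adverse event (paroxetine-referenced odds ratios).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .absolute import CLIP_EPS, AbsoluteModel
from .crosswalk import CrosswalkTable, convert_score
from .errors import BoundaryError, ConfigurationError, InvalidArgumentError
from .nma import ModifierModel, RelativeEffects
from .treatments import REFERENCE_AE, REFERENCE_EFFICACY

HDRS_BOUNDS = (0.0, 52.0)

__all__ = ["PredictionSet", "combine_continuous", "combine_binary", "predict_profile"]


def combine_continuous(absolute_ref: float, delta: float) -> float:
    """Absolute HDRS under another drug: reference prediction plus delta."""
    if not (np.isfinite(absolute_ref) and np.isfinite(delta)):
        raise InvalidArgumentError("inputs must be finite")
    return float(np.clip(absolute_ref + delta, *HDRS_BOUNDS))


def combine_binary(p_ref: float, odds_ratio: float) -> float:
    """Absolute event probability under another drug: odds times OR.

    ``p = sigma(logit(p_ref) + log OR)``. The reference probability must lie
    strictly inside (0, 1) — model outputs are clamped upstream.
    """
    if not (np.isfinite(p_ref) and np.isfinite(odds_ratio)):
        raise InvalidArgumentError("inputs must be finite")
    if not 0.0 < p_ref < 1.0:
        raise BoundaryError(f"p_ref must be in (0,1), got {p_ref}")
    if odds_ratio <= 0:
        raise InvalidArgumentError(f"odds ratio must be > 0, got {odds_ratio}")
    odds = p_ref / (1.0 - p_ref) * odds_ratio
    return float(odds / (1.0 + odds))


@dataclass
class PredictionSet:
    """Per-patient predictions for every candidate drug and outcome."""

    patient_id: str
    drugs: dict[str, dict]  # drug -> {expected_hdrs_8wk, p_discontinue, p_ae: {...}}
    provenance: dict = field(default_factory=dict)

    def expected_hdrs(self, drug: str) -> float:
        return self.drugs[drug]["expected_hdrs_8wk"]

    def p_discontinue(self, drug: str) -> float:
        return self.drugs[drug]["p_discontinue"]

    def p_ae(self, drug: str, ae: str) -> float:
        return self.drugs[drug]["p_ae"][ae]

    @property
    def modeled_aes(self) -> list[str]:
        any_drug = next(iter(self.drugs.values()))
        return sorted(any_drug["p_ae"])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {"patient_id": self.patient_id, "drugs": self.drugs,
                   "provenance": self.provenance}
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for drug, d in sorted(self.drugs.items()):
            rows.append((self.patient_id, drug, "expected_hdrs_8wk", d["expected_hdrs_8wk"]))
            rows.append((self.patient_id, drug, "p_discontinue", d["p_discontinue"]))
            for ae, p in sorted(d["p_ae"].items()):
                rows.append((self.patient_id, drug, f"p_ae_{ae}", p))
        return pd.DataFrame(rows, columns=["patient", "drug", "outcome", "value"])


def _clamp_prob(p: float) -> float:
    return float(np.clip(p, CLIP_EPS, 1.0 - CLIP_EPS))


def predict_profile(patient: Mapping[str, float],
                    absolute_models: Mapping[str, object],
                    relative_effects: Mapping[str, object],
                    drug_list: Sequence[str],
                    crosswalk: CrosswalkTable | None = None,
                    feature_row: pd.DataFrame | None = None,
                    patient_id: str = "patient",
                    provenance: Mapping | None = None) -> PredictionSet:
    """Predict every outcome for every drug for one (complete) patient.

    Parameters
    ----------
    patient : covariate mapping used for the patient-specific efficacy delta.
    absolute_models : ``{"efficacy": AbsoluteModel, "discontinuation":
        AbsoluteModel, "ae": {ae_name: AbsoluteModel}}``; the efficacy model
        predicts on the PHQ-9 scale when ``crosswalk`` is given, otherwise
        directly on HDRS.
    relative_effects : ``{"efficacy": ModifierModel, "discontinuation":
        RelativeEffects (log-OR vs fluoxetine), "ae": {ae_name:
        RelativeEffects (log-OR vs paroxetine)}}``.
    drug_list : candidate drugs; each must be covered by every component.
    feature_row : one-row design matrices per absolute model, keyed like
        ``absolute_models`` (required because each model was fit on its own
        design); a plain mapping of arrays is accepted.
    """
    feats = feature_row

    def _absolute(key: str, model: AbsoluteModel) -> float:
        if isinstance(feats, Mapping) and key in feats:
            X = feats[key]
        elif feats is None:
            raise ConfigurationError(f"no feature row supplied for component {key!r}")
        else:
            X = feats  # a single design shared by all absolute models
        return float(np.asarray(model.predict(X)).ravel()[0])

    eff_model: AbsoluteModel = absolute_models["efficacy"]
    modifier: ModifierModel = relative_effects["efficacy"]
    drop_model: AbsoluteModel = absolute_models["discontinuation"]
    drop_re: RelativeEffects = relative_effects["discontinuation"]
    ae_models: Mapping[str, AbsoluteModel] = absolute_models.get("ae", {})
    ae_res: Mapping[str, RelativeEffects] = relative_effects.get("ae", {})
    if set(ae_models) != set(ae_res):
        raise ConfigurationError(
            f"adverse-event components disagree: models for {sorted(ae_models)} "
            f"vs relative effects for {sorted(ae_res)}")

    for drug in drug_list:
        if drug != modifier.reference and drug not in modifier.treatments:
            raise ConfigurationError(f"drug {drug!r} missing from the efficacy NMA")
        if drug not in drop_re.effects:
            raise ConfigurationError(f"drug {drug!r} missing from the discontinuation NMA")
        for ae, re_ in ae_res.items():
            if drug not in re_.effects:
                raise ConfigurationError(f"drug {drug!r} missing from the {ae!r} NMA")

    abs_eff = _absolute("efficacy", eff_model)
    hdrs_ref = (convert_score(abs_eff, crosswalk, "phq9_to_hdrs")
                if crosswalk is not None else abs_eff)
    p_drop_ref = _clamp_prob(_absolute("discontinuation", drop_model))
    p_ae_ref = {ae: _clamp_prob(_absolute(ae, m)) for ae, m in ae_models.items()}

    drugs: dict[str, dict] = {}
    for drug in drug_list:
        delta, _ = modifier.predict_delta(patient, drug)
        hdrs = hdrs_ref if drug == modifier.reference else combine_continuous(hdrs_ref, delta)
        if drug == drop_re.reference:
            p_drop = p_drop_ref
        else:
            p_drop = combine_binary(p_drop_ref, float(np.exp(drop_re.estimate(drug))))
        p_ae = {}
        for ae, re_ in ae_res.items():
            if drug == re_.reference:
                p_ae[ae] = p_ae_ref[ae]
            else:
                p_ae[ae] = combine_binary(p_ae_ref[ae], float(np.exp(re_.estimate(drug))))
        drugs[drug] = {"expected_hdrs_8wk": float(np.clip(hdrs, *HDRS_BOUNDS)),
                       "p_discontinue": p_drop, "p_ae": p_ae}
    return PredictionSet(patient_id=patient_id, drugs=drugs,
                         provenance=dict(provenance or {}))
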