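"""End-to-end pipeline: simulate -> impute -> fit -> NMA -> combine -> recommend.

:func:`run_pipeline` executes the whole backend on synthetic data with known
ground truth and writes every artifact (models, validation reports,
relative effects, predictions, recommendation, rendered report, manifest
with content hashes) into a directory. All randomness is fanned out
deterministically from the single seed in the config, so rerunning the same
config reproduces every deterministic artifact byte for byte.

The defaults are a desk-scale demonstration: a few thousand EHR records and
a 20-study trial network rather than the hundreds of thousands of records a
production deployment would ingest; the statistical machinery is identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import synthetic
from .absolute import (
    AbsoluteModel,
    ModelSpec,
    ScreenConfig,
    build_design,
    cross_validate,
    fit_model,
    screen_adverse_events,
)
from .combine import PredictionSet, predict_profile
from .crosswalk import default_crosswalk, load_crosswalk
from .errors import ConfigurationError, ConsistencyError
from .mcda import PreferenceInput, Recommendation, recommend
from .nma import fit_ad_nma, fit_ipd_nma
from .profiles import PatientProfile
from .synthetic import TruthParameters, default_truth
from .treatments import ANTIDEPRESSANTS, REFERENCE_AE, REFERENCE_EFFICACY

logger = logging.getLogger("petrushka")

#: Predictors for the EHR-based absolute models.
EHR_CONTINUOUS = ("age", "bmi", "phq9_total", "hdrs_total")
EHR_PASSTHROUGH = (
    "sex_female", "socioeconomic_quintile",
    "hdrs_item_3", "hdrs_item_4", "hdrs_item_6", "hdrs_item_10",
    "hdrs_item_11", "hdrs_item_13", "hdrs_item_17",
    *synthetic.BINARY_FLAGS,
)

#: Predictors for the trial-based adverse-event models. Deliberately lean:
#: the reference arm of a desk-scale network supports few parameters.
IPD_CONTINUOUS = ("age", "hdrs_total")
IPD_PASSTHROUGH = ("sex_female",)


class PipelineConfig(BaseModel):
    """Schema-validated configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_ehr: int = 2000
    ipd_studies: int = 20
    ipd_per_arm: int = 250
    ad_per_arm: int = 400
    missing_rate: float = 0.0
    m_imputations: int = 3
    imputation_sweeps: int = 3
    k_folds: int = 10
    model_kind: str = "ridge"          # "ridge" | "stack" for the EHR models
    ridge_lambda: float | None = None  # fixed penalty; None = inner-CV selection
    drug_list: list[str] = Field(default_factory=lambda: list(ANTIDEPRESSANTS))
    ae_names: list[str] = Field(default_factory=lambda: list(synthetic.DEFAULT_AE_SUBSET))
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    anchors: str = "local"
    crosswalk_path: str | None = None
    truth_overrides: dict = Field(default_factory=dict)
    patient: dict | None = None
    prefs: dict = Field(default_factory=dict)
    #: ScreenConfig overrides; ``n_params`` defaults to the fitted AE design
    #: size, and the anticipated Cox-Snell R^2 to 0.15 for these models.
    screening: dict = Field(default_factory=lambda: {"r2_cs": 0.15})

    def model_post_init(self, __context) -> None:
        bad = [d for d in self.drug_list if d not in ANTIDEPRESSANTS]
        if bad:
            raise ConfigurationError(f"drug_list entries outside the canonical 16: {bad}")
        if self.model_kind not in ("ridge", "stack"):
            raise ConfigurationError(f"model_kind must be ridge or stack, got {self.model_kind!r}")


DEMO_PATIENT = dict(
    age=47, sex="female", phq9_total=18, hdrs_total=26,
    hdrs_items={3: 1, 4: 2, 6: 1, 10: 3, 11: 2, 13: 2, 17: 0},
    past_antidepressant=True, anxiety=True, nsaids=True,
)


class _EnsembleModel:
    """Average predictions across per-imputation fits (Rubin-style pooling
    of the prediction, which is the quantity the decision aid consumes)."""

    def __init__(self, models: Sequence[AbsoluteModel]):
        self.models = list(models)
        self.family = self.models[0].family

    def predict(self, X, clip: bool = True):
        return np.mean([m.predict(X, clip=clip) for m in self.models], axis=0)


def _spec(kind: str, family: str, seed: int, lam: float | None = None) -> ModelSpec:
    ridge_params = {} if lam is None else {"lam": lam}
    if kind == "stack":
        base = [ModelSpec("ridge", family, dict(ridge_params)),
                ModelSpec("mlp", family, {"seed": seed})]
        return ModelSpec("stack", family, {"base": [vars(s) | {} for s in base],
                                           "seed": seed})
    return ModelSpec("ridge", family, dict(ridge_params))


def _restrict_prefs(prefs: PreferenceInput, included: Sequence[str]) -> PreferenceInput:
    """Drop selected adverse events that failed screening, re-packing ranks
    into a permutation of 1..k (relative order preserved)."""
    keep = [i for i, a in enumerate(prefs.selected_aes) if a in included]
    sel = [prefs.selected_aes[i] for i in keep]
    ranks = None
    if prefs.ranks is not None and sel:
        kept = [prefs.ranks[i] for i in keep]
        order = sorted(range(len(kept)), key=kept.__getitem__)
        ranks = [0] * len(kept)
        for pos, j in enumerate(order, start=1):
            ranks[j] = pos
    return PreferenceInput(selected_aes=sel, ranks=ranks,
                           clinician_exclusions=prefs.clinician_exclusions,
                           elicit_opt_out=prefs.elicit_opt_out)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute every stage and write artifacts; returns the output directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)
    truth = default_truth(seed=seed, **config.truth_overrides)
    crosswalk = (load_crosswalk(config.crosswalk_path) if config.crosswalk_path
                 else default_crosswalk())
    artifacts: dict[str, Path] = {}

    def save(name: str, text: str) -> None:
        p = out / name
        p.write_text(text)
        artifacts[name] = p
        logger.info("stage artifact %s sha256=%s", name, _sha256(p))

    save("truth.json", truth.to_json())

    # -- simulate -----------------------------------------------------------
    cohort = synthetic.generate_ehr_cohort(config.n_ehr, truth, seed=seed + 1)
    ipd = synthetic.generate_rct_ipd(config.ipd_studies, config.ipd_per_arm,
                                     truth=truth, seed=seed + 2,
                                     ae_names=config.ae_names)
    ad_dropout = synthetic.generate_ad_network(config.ipd_studies, config.ad_per_arm,
                                               truth, seed=seed + 3, outcome="dropout")
    logger.info("simulated cohort n=%d, IPD rows=%d", len(cohort), len(ipd))

    # -- impute -------------------------------------------------------------
    if config.missing_rate > 0:
        from .impute import impute_multiple

        observed = synthetic.inject_missingness(cohort, "MCAR", config.missing_rate,
                                                seed=seed + 4)
        imputed = impute_multiple(observed, m=config.m_imputations, seed=seed + 5,
                                  sweeps=config.imputation_sweeps,
                                  exclude=("patient_id", "treatment", "sex"))
        ehr_sets = imputed.datasets
    else:
        ehr_sets = [cohort]

    # -- absolute models on the EHR extract ---------------------------------
    X0, eff_info = build_design(ehr_sets[0], EHR_CONTINUOUS, EHR_PASSTHROUGH)
    y_eff = ehr_sets[0]["outcome_phq9_8wk"].to_numpy(dtype=float)
    y_drop = ehr_sets[0]["discontinued_8wk"].to_numpy(dtype=float)
    eff_spec = _spec(config.model_kind, "continuous", seed, config.ridge_lambda)
    drop_spec = _spec("ridge", "binary", seed, config.ridge_lambda)

    eff_models, drop_models = [], []
    for i, ds in enumerate(ehr_sets):
        Xi = eff_info.transform(ds)
        eff_models.append(fit_model(eff_spec, Xi, ds["outcome_phq9_8wk"].to_numpy(float),
                                    seed=seed + 10 + i, bounds=(0.0, 27.0)))
        drop_models.append(fit_model(drop_spec, Xi, ds["discontinued_8wk"].to_numpy(float),
                                     seed=seed + 10 + i))
    eff_model = _EnsembleModel(eff_models)
    drop_model = _EnsembleModel(drop_models)

    validation = {
        "efficacy": vars(cross_validate(eff_spec, X0, y_eff, k=config.k_folds,
                                        seed=seed + 20)),
        "discontinuation": vars(cross_validate(drop_spec, X0, y_drop,
                                               k=config.k_folds, seed=seed + 21)),
    }

    # -- adverse-event models on the trial reference arm ---------------------
    parox = ipd[ipd["treatment"] == REFERENCE_AE]
    Xp, ae_info = build_design(parox, IPD_CONTINUOUS, IPD_PASSTHROUGH)
    ae_validation, ae_models_all = {}, {}
    for ae in config.ae_names:
        y = parox[f"ae_{ae}"].to_numpy(dtype=float)
        if len(np.unique(y)) < 2:
            continue
        spec = _spec("ridge", "binary", seed, config.ridge_lambda)
        k = min(config.k_folds, int(min((y == 1).sum(), (y == 0).sum())))
        if k < 2:
            continue
        ae_validation[ae] = cross_validate(spec, Xp, y, k=k, seed=seed + 30)
        ae_models_all[ae] = fit_model(spec, Xp, y, seed=seed + 30)
    screening = dict(config.screening)
    screening.setdefault("n_params", Xp.shape[1] + 1)
    screen = screen_adverse_events(ipd, ae_validation, config=ScreenConfig(**screening))
    included_aes = screen.included
    validation["adverse_events"] = {ae: vars(v) for ae, v in ae_validation.items()}
    save("validation.json", json.dumps(validation, indent=2, sort_keys=True, default=list))
    save("ae_screen.json", screen.table.to_json(orient="records", indent=2))

    # -- network meta-analyses ----------------------------------------------
    modifier = fit_ipd_nma(ipd, REFERENCE_EFFICACY, modifiers=("hdrs_total", "age"))
    drop_re = fit_ad_nma(ad_dropout, REFERENCE_EFFICACY)
    ae_re = {}
    for j, ae in enumerate(included_aes):
        net = synthetic.generate_ad_network(config.ipd_studies, config.ad_per_arm,
                                            truth, seed=seed + 40 + j, outcome=ae)
        ae_re[ae] = fit_ad_nma(net, REFERENCE_AE)
    save("modifier_model.json", modifier.to_json())
    save("relative_effects_dropout.json", drop_re.to_json())
    for ae, re_ in ae_re.items():
        save(f"relative_effects_ae_{ae}.json", re_.to_json())

    # -- per-patient predictions and recommendation -------------------------
    covered = (set(ipd["treatment"]) & set(ad_dropout["treatment"])
               - {REFERENCE_EFFICACY}) | {REFERENCE_EFFICACY}
    drug_list = [d for d in config.drug_list if d in covered]
    dropped = sorted(set(config.drug_list) - set(drug_list))
    if dropped:
        logger.warning("drugs outside the simulated network dropped: %s", dropped)
    if not drug_list:
        raise ConfigurationError("no configured drug is covered by the trial network")

    patient = PatientProfile(**(config.patient or DEMO_PATIENT))
    row = patient.to_row()
    feature_rows = {"efficacy": eff_info.transform(row),
                    "discontinuation": eff_info.transform(row),
                    **{ae: ae_info.transform(row) for ae in included_aes}}
    pred = predict_profile(
        patient.covariates(),
        {"efficacy": eff_model, "discontinuation": drop_model,
         "ae": {ae: ae_models_all[ae] for ae in included_aes}},
        {"efficacy": modifier, "discontinuation": drop_re, "ae": ae_re},
        drug_list=drug_list, crosswalk=crosswalk,
        feature_row=feature_rows, patient_id="demo_patient",
        provenance={"seed": seed, "model_kind": config.model_kind})
    save("predictions.json", pred.to_json())

    prefs = PreferenceInput(**config.prefs) if config.prefs else PreferenceInput(
        selected_aes=included_aes[: min(3, len(included_aes))])
    prefs = _restrict_prefs(prefs, included_aes)
    rec = recommend(pred, prefs, top_level=tuple(config.weights), anchors=config.anchors)
    save("recommendation.json", rec.to_json())
    save("report.txt", render_report(rec, pred))

    manifest = {"config": json.loads(config.model_dump_json()),
                "artifacts": {n: _sha256(p) for n, p in sorted(artifacts.items())}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------


def natural_frequency(p: float, per: int = 100) -> str:
    """Render a probability as a natural frequency ('25 in 100')."""
    return f"{int(round(p * per))} in {per}"


def render_report(rec: Recommendation, pred: PredictionSet) -> str:
    """Human-readable report: top-3 with dots, patient-facing breakdown of
    the selected adverse events, and a clinician-only table of every modeled
    event. Absolute risks are shown as natural frequencies."""
    for d in rec.ranking:
        if d not in pred.drugs:
            raise ConsistencyError(f"ranked drug {d!r} has no predictions")
    lines = ["Personalized antidepressant recommendation", "=" * 43, ""]
    lines.append("Top recommendations (dots = strength of recommendation):")
    for i, d in enumerate(rec.top3, 1):
        dots = "●" * rec.dot_strength[d] + "○" * (5 - rec.dot_strength[d])
        lines.append(f"  {i}. {d:<14} {dots}  value={rec.values[d]:.3f}  "
                     f"expected HDRS {pred.expected_hdrs(d):.1f}, "
                     f"stops treatment: {natural_frequency(pred.p_discontinue(d))}")
    if rec.excluded:
        lines.append(f"\nExcluded by the clinician: {', '.join(rec.excluded)}")
    lines.append("\nSide effects selected by the patient (chance out of 100):")
    for d in rec.top3:
        parts = [f"{ae.replace('_', ' ')}: {natural_frequency(p)}"
                 for ae, p in sorted(rec.ae_breakdown.get(d, {}).items())]
        lines.append(f"  {d:<14} " + ("; ".join(parts) if parts else "(none selected)"))
    lines.append("\n[clinician view] all modeled adverse events:")
    for d in rec.top3:
        parts = [f"{ae.replace('_', ' ')}: {natural_frequency(p)}"
                 for ae, p in sorted(pred.drugs[d]["p_ae"].items())]
        lines.append(f"  {d:<14} " + "; ".join(parts))
    return "\n".join(lines) + "\n"
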