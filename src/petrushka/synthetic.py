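"""Synthetic EHR cohorts, trial IPD, and aggregate arm-level networks.

Real data behind this kind of decision aid (primary-care EHR, pharma trial
IPD, aggregate dropout/adverse-event networks) are access-controlled, so the
package ships generators with *known* ground truth. Every generator is a pure
function of its arguments and a seed; the generating parameters live in
:class:`TruthParameters` and round-trip through JSON so recovery tests can
assert against them.

The EHR generator emulates a primary-care fluoxetine cohort: covariate
marginals are configured to the moments of the trial-population description
(age 44.8 ± 14.2, baseline HDRS 23.85 ± 3.99, 64.3% female), the 8-week
severity outcome is simulated directly on the PHQ-9 scale (primary-care
records measure PHQ-9; conversion to HDRS happens downstream), and all-cause
discontinuation is a logistic draw. The IPD generator emits a connected
network of randomized trials with study-level random treatment effects of
variance tau^2 and optional treatment-by-covariate interactions; the
aggregate generator emits binomial arm counts for event outcomes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import InvalidArgumentError, NetworkError
from .treatments import (
    ADVERSE_EVENTS,
    ANTIDEPRESSANTS,
    PLACEBO,
    REFERENCE_AE,
    REFERENCE_EFFICACY,
    TREATMENTS,
)

# ---------------------------------------------------------------------------
# Covariate marginals (means/SDs of the emulated populations)
# ---------------------------------------------------------------------------

#: (mean, sd, low, high) for truncated-normal continuous covariates.
CONTINUOUS_MARGINALS: dict[str, tuple[float, float, float, float]] = {
    "age": (44.8, 14.2, 18.0, 74.0),
    "bmi": (27.0, 5.0, 15.0, 55.0),
    "hdrs_total": (23.85, 3.99, 0.0, 52.0),
}

#: (mean, sd, low, high) for the seven HDRS items carried as predictors.
HDRS_ITEM_MARGINALS: dict[str, tuple[float, float, int, int]] = {
    "hdrs_item_3": (0.92, 0.86, 0, 4),   # suicide
    "hdrs_item_4": (1.32, 0.80, 0, 2),   # insomnia, early night
    "hdrs_item_6": (1.25, 0.79, 0, 2),   # insomnia, early morning
    "hdrs_item_10": (2.25, 0.75, 0, 4),  # anxiety, psychic
    "hdrs_item_11": (1.75, 0.80, 0, 4),  # anxiety, somatic
    "hdrs_item_13": (1.65, 0.54, 0, 2),  # general somatic symptoms
    "hdrs_item_17": (0.25, 0.48, 0, 2),  # insight
}

PROP_FEMALE = 0.643

ETHNICITY_CODES = ("white", "asian", "black", "mixed", "other")
ETHNICITY_PROBS = (0.82, 0.08, 0.04, 0.03, 0.03)
SMOKING_LEVELS = ("never", "ex", "current")
SMOKING_PROBS = (0.52, 0.25, 0.23)

HISTORY_FLAGS: dict[str, float] = {
    "past_antidepressant": 0.45,
    "past_ssri": 0.35,
    "past_fluoxetine": 0.15,
    "past_psychotherapy": 0.25,
    "secondary_care_referral": 0.12,
    "childhood_maltreatment": 0.10,
}

COMORBIDITY_FLAGS: dict[str, float] = {
    "anxiety": 0.40,
    "chronic_inflammatory_disease": 0.08,
    "coronary_heart_disease": 0.05,
    "diabetes": 0.07,
    "epilepsy_seizures": 0.02,
    "hypothyroidism": 0.05,
    "migraine": 0.12,
    "stroke_tia": 0.02,
}

CO_MEDICATION_FLAGS: dict[str, float] = {
    "anticoagulants": 0.03,
    "anticonvulsants": 0.04,
    "antihypertensives": 0.15,
    "aspirin": 0.08,
    "bisphosphonates": 0.03,
    "hypnotics_anxiolytics": 0.12,
    "hrt": 0.04,
    "nsaids": 0.18,
    "oral_contraceptives": 0.10,
    "statins": 0.12,
}

BINARY_FLAGS: dict[str, float] = {**HISTORY_FLAGS, **COMORBIDITY_FLAGS, **CO_MEDICATION_FLAGS}

#: Centres used in all linear predictors (so intercepts stay interpretable).
COVARIATE_CENTRES: dict[str, float] = {
    "age": 44.8,
    "bmi": 27.0,
    "hdrs_total": 23.85,
    "phq9_total": 14.0,
    "sex_female": PROP_FEMALE,
    **{k: (m[0]) for k, m in HDRS_ITEM_MARGINALS.items()},
    **BINARY_FLAGS,
}

OUTCOME_COLUMNS = ("outcome_phq9_8wk", "discontinued_8wk")


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


def _default_treatment_effects() -> dict[str, float]:
    """Mean 8-week HDRS difference vs fluoxetine (negative = more effective)."""
    return {
        "agomelatine": -0.6,
        "amitriptyline": -1.2,
        "bupropion": -0.2,
        "citalopram": -0.3,
        "clomipramine": -0.8,
        "duloxetine": -0.5,
        "escitalopram": -1.0,
        "fluoxetine": 0.0,
        "fluvoxamine": 0.2,
        "imipramine": -0.4,
        "mirtazapine": -1.1,
        "paroxetine": -0.6,
        "sertraline": -0.9,
        "trazodone": 0.3,
        "venlafaxine": -1.0,
        "vortioxetine": -0.7,
        "placebo": 2.2,
    }


def _default_log_ors_dropout() -> dict[str, float]:
    """Log odds ratios of 8-week all-cause discontinuation vs fluoxetine."""
    return {
        "agomelatine": -0.15,
        "amitriptyline": 0.20,
        "bupropion": 0.05,
        "citalopram": -0.05,
        "clomipramine": 0.30,
        "duloxetine": 0.10,
        "escitalopram": -0.10,
        "fluoxetine": 0.0,
        "fluvoxamine": 0.25,
        "imipramine": 0.22,
        "mirtazapine": -0.02,
        "paroxetine": 0.04,
        "sertraline": -0.08,
        "trazodone": 0.28,
        "venlafaxine": 0.06,
        "vortioxetine": -0.12,
        "placebo": 0.15,
    }


def _default_log_ors_ae(ae_names: Sequence[str]) -> dict[str, dict[str, float]]:
    """Per-adverse-event log odds ratios vs paroxetine (the AE reference).

    Deterministic spread so each event discriminates between drugs without
    being tied to any one seed.
    """
    out: dict[str, dict[str, float]] = {}
    for j, ae in enumerate(ae_names):
        per_drug: dict[str, float] = {}
        for i, t in enumerate(TREATMENTS):
            if t == REFERENCE_AE:
                per_drug[t] = 0.0
            else:
                # fixed deterministic pattern in [-0.6, 0.6]
                per_drug[t] = round(0.6 * np.sin(1.3 * i + 0.7 * j), 3)
        out[ae] = per_drug
    return out


DEFAULT_AE_SUBSET: tuple[str, ...] = ADVERSE_EVENTS[:6]


def _default_ae_baseline_probs() -> dict[str, float]:
    """Reference-arm event probabilities for all 30 events (0.06-0.20)."""
    return {ae: round(0.13 + 0.07 * np.sin(2.1 * j + 0.4), 3)
            for j, ae in enumerate(ADVERSE_EVENTS)}


@dataclass
class TruthParameters:
    """Known generating parameters for every synthetic dataset.

    All treatment effects are expressed against the analysis reference
    (fluoxetine for efficacy and dropout; paroxetine for adverse events), with
    the reference's own entry fixed at 0.
    """

    treatment_effects: dict[str, float] = field(default_factory=_default_treatment_effects)
    log_ors_dropout: dict[str, float] = field(default_factory=_default_log_ors_dropout)
    log_ors_ae: dict[str, dict[str, float]] = field(
        default_factory=lambda: _default_log_ors_ae(ADVERSE_EVENTS)
    )
    #: Effects of (centred) covariates on the 8-week PHQ-9 outcome in the EHR.
    covariate_coefficients: dict[str, float] = field(
        default_factory=lambda: {
            "phq9_total": 0.55,
            "age": 0.02,
            "sex_female": -0.3,
            "past_antidepressant": 0.8,
            "anxiety": 0.5,
        }
    )
    #: Effects of (centred) covariates on the EHR discontinuation log-odds;
    #: sized so the true model discriminates like published ones (AUC ~0.65).
    dropout_covariate_coefficients: dict[str, float] = field(
        default_factory=lambda: {"age": -0.02, "hdrs_total": 0.08,
                                 "past_antidepressant": 0.6, "anxiety": 0.4}
    )
    #: Effects of (centred) covariates on every adverse-event log-odds.
    ae_covariate_coefficients: dict[str, float] = field(
        default_factory=lambda: {"age": 0.035, "sex_female": 0.6, "hdrs_total": 0.05}
    )
    #: Treatment-by-covariate interactions (shared across non-reference arms).
    modifier_coefficients: dict[str, float] = field(
        default_factory=lambda: {"hdrs_total": -0.10, "age": 0.01}
    )
    #: Prognostic (arm-independent) covariate effects in the trial outcome model.
    prognostic_coefficients: dict[str, float] = field(
        default_factory=lambda: {"hdrs_total": 0.45, "age": 0.01}
    )
    tau2: float = 0.04
    baseline_event_probs: dict = field(
        default_factory=lambda: {"dropout": 0.25, "ae": _default_ae_baseline_probs()}
    )
    ehr_intercept: float = 12.0       # mean 8-week PHQ-9 on fluoxetine at the centre
    ehr_noise_sd: float = 3.0         # residual SD consistent with reported CV error
    ipd_intercept: float = 16.0       # mean 8-week HDRS on fluoxetine at the centre
    ipd_noise_sd: float = 6.0
    study_baseline_sd: float = 1.0    # SD of trial-level baseline shifts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau2 < 0:
            raise InvalidArgumentError("tau2 must be >= 0")
        if self.treatment_effects.get(REFERENCE_EFFICACY, 0.0) != 0.0:
            raise InvalidArgumentError("reference drug must have zero effect vs itself")
        if self.log_ors_dropout.get(REFERENCE_EFFICACY, 0.0) != 0.0:
            raise InvalidArgumentError("reference drug must have zero dropout log-OR")
        for ae, ors in self.log_ors_ae.items():
            if ors.get(REFERENCE_AE, 0.0) != 0.0:
                raise InvalidArgumentError(f"AE reference must have zero log-OR ({ae})")
        probs = [self.baseline_event_probs["dropout"], *self.baseline_event_probs["ae"].values()]
        if not all(0.0 < p < 1.0 for p in probs):
            raise InvalidArgumentError("baseline event probabilities must lie in (0,1)")

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "TruthParameters":
        """Load from a JSON string or a path to a JSON file."""
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text()
        else:
            text = str(source)
        return cls(**json.loads(text))


def default_truth(seed: int = 0, **overrides) -> TruthParameters:
    """The default study conditions; ``overrides`` replace individual fields."""
    return TruthParameters(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Sampling helpers
# ---------------------------------------------------------------------------


def _matched_truncnorm(mean: float, sd: float, lo: float, hi: float,
                       size: int, rng: np.random.Generator) -> np.ndarray:
    """Truncated-normal draws whose *truncated* mean equals ``mean``.

    The location parameter is shifted so that truncation at [lo, hi] does not
    bias the configured mean (the shift is solved by root finding).
    """
    def trunc_mean(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    try:
        loc = optimize.brentq(trunc_mean, lo, hi, xtol=1e-10)
    except ValueError:  # target mean not attainable inside the bounds
        loc = mean
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def _discrete_item(mean: float, sd: float, lo: int, hi: int,
                   size: int, rng: np.random.Generator) -> np.ndarray:
    """Integer item scores from a rounded matched truncated normal."""
    x = _matched_truncnorm(mean, sd, lo - 0.49, hi + 0.49, size, rng)
    return np.clip(np.rint(x), lo, hi).astype(int)


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _centred(df: pd.DataFrame, coefs: Mapping[str, float]) -> np.ndarray:
    """Linear predictor sum coef * (x - centre) over named covariates."""
    lp = np.zeros(len(df))
    for name, beta in coefs.items():
        if name not in df.columns:
            raise InvalidArgumentError(f"coefficient on unknown covariate {name!r}")
        centre = COVARIATE_CENTRES.get(name, 0.0)
        lp += beta * (df[name].to_numpy(dtype=float) - centre)
    return lp


def _draw_covariates(n: int, rng: np.random.Generator,
                     columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Draw the full covariate block (independent marginals)."""
    cols: dict[str, np.ndarray | pd.Series] = {}
    cols["age"] = _matched_truncnorm(*CONTINUOUS_MARGINALS["age"], n, rng)
    cols["sex"] = np.where(rng.random(n) < PROP_FEMALE, "female", "male")
    cols["ethnicity"] = rng.choice(ETHNICITY_CODES, size=n, p=ETHNICITY_PROBS)
    cols["socioeconomic_quintile"] = rng.integers(1, 6, size=n)
    cols["bmi"] = _matched_truncnorm(*CONTINUOUS_MARGINALS["bmi"], n, rng)
    cols["smoking"] = rng.choice(SMOKING_LEVELS, size=n, p=SMOKING_PROBS)
    hdrs = _matched_truncnorm(*CONTINUOUS_MARGINALS["hdrs_total"], n, rng)
    cols["hdrs_total"] = np.clip(np.rint(hdrs), 0, 52).astype(int)
    # PHQ-9 correlated with HDRS severity, on its own 0-27 scale
    phq9 = 0.5 * cols["hdrs_total"] + 2.0 + rng.normal(0.0, 2.0, n)
    cols["phq9_total"] = np.clip(np.rint(phq9), 0, 27).astype(int)
    for item, (m, s, lo, hi) in HDRS_ITEM_MARGINALS.items():
        cols[item] = _discrete_item(m, s, lo, hi, n, rng)
    for flag, p in BINARY_FLAGS.items():
        cols[flag] = (rng.random(n) < p).astype(int)
    # age at first diagnosis: uniformly between 16 and current age
    age = np.asarray(cols["age"])
    cols["age_first_diagnosis"] = 16.0 + rng.random(n) * (age - 16.0)
    df = pd.DataFrame(cols)
    df["sex_female"] = (df["sex"] == "female").astype(int)
    if columns is not None:
        df = df[list(columns)]
    return df


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def generate_ehr_cohort(n: int, truth: TruthParameters | None = None,
                        seed: int = 0) -> pd.DataFrame:
    """Simulate an EHR-like fluoxetine cohort with 8-week outcomes.

    One row per patient: the covariate block, ``treatment`` (constant
    reference drug), the 8-week PHQ-9 outcome (integer 0-27, linear model on
    centred covariates plus Gaussian noise), and an 8-week discontinuation
    flag (logistic model). Deterministic given ``seed``.
    """
    if n < 1:
        raise InvalidArgumentError(f"n must be >= 1, got {n}")
    truth = truth or default_truth()
    rng = np.random.default_rng(seed)
    df = _draw_covariates(n, rng)
    df.insert(0, "patient_id", np.arange(n))
    df["treatment"] = REFERENCE_EFFICACY

    lp = truth.ehr_intercept + _centred(df, truth.covariate_coefficients)
    y = lp + rng.normal(0.0, truth.ehr_noise_sd, n)
    df["outcome_phq9_8wk"] = np.clip(np.rint(y), 0, 27).astype(int)

    p0 = truth.baseline_event_probs["dropout"]
    lp_d = _logit(p0) + _centred(df, truth.dropout_covariate_coefficients)
    df["discontinued_8wk"] = (rng.random(n) < _expit(lp_d)).astype(int)
    return df


def default_network_design(n_studies: int = 20) -> list[tuple[str, str]]:
    """A connected two-arm design: a fluoxetine hub over all 17 nodes.

    The first 16 studies pair fluoxetine with each other node; additional
    studies cycle through active-active and placebo comparisons. Scaled down
    from the hundreds of trials a real network holds, but preserving its
    shape: one well-connected hub plus off-hub closing loops.
    """
    others = [t for t in TREATMENTS if t != REFERENCE_EFFICACY]
    hub = [(REFERENCE_EFFICACY, t) for t in others]
    # paroxetine is deliberately the best-sampled active node (it is the
    # adverse-event reference, mirroring its outsized arm in real trial data)
    extras = [
        ("paroxetine", "sertraline"),
        ("paroxetine", PLACEBO),
        ("paroxetine", "escitalopram"),
        ("paroxetine", "venlafaxine"),
        ("sertraline", "escitalopram"),
        ("amitriptyline", "imipramine"),
        ("duloxetine", "venlafaxine"),
        ("vortioxetine", PLACEBO),
    ]
    design: list[tuple[str, str]] = []
    i = 0
    while len(design) < n_studies:
        pool = hub if i < len(hub) else extras
        design.append(pool[(i - len(hub)) % len(extras)] if i >= len(hub) else hub[i])
        i += 1
    return design[:n_studies]


def _check_design(design: Sequence[Sequence[str]]) -> None:
    g = nx.Graph()
    for arms in design:
        arms = list(arms)
        if len(set(arms)) < 2:
            raise InvalidArgumentError(f"study needs >=2 distinct arms, got {arms}")
        for t in arms:
            if t not in TREATMENTS:
                raise InvalidArgumentError(f"unknown treatment {t!r} in design")
        for a in arms:
            for b in arms:
                if a != b:
                    g.add_edge(a, b)
    comps = [sorted(c) for c in nx.connected_components(g)]
    if len(comps) > 1:
        raise NetworkError(f"design network is disconnected: {comps}", components=comps)


IPD_COVARIATES = ("age", "sex", "sex_female", "hdrs_total") + tuple(HDRS_ITEM_MARGINALS)


def generate_rct_ipd(n_studies: int = 20, per_arm_n: int = 200,
                     design: Sequence[Sequence[str]] | None = None,
                     truth: TruthParameters | None = None,
                     seed: int = 0,
                     ae_names: Sequence[str] | None = None) -> pd.DataFrame:
    """Simulate patient-level randomized-trial data over a treatment network.

    Outcome model (8-week HDRS), for patient i in arm t of study s::

        y = intercept + b_s + sum_c prognostic_c (x_c - centre_c)
            + 1[t != ref] * (delta_t + u_st + sum_c modifier_c (x_c - centre_c))
            + eps

    with ``b_s ~ N(0, study_baseline_sd^2)``, ``u_st ~ N(0, tau^2)`` drawn per
    non-reference arm (the conditional parameterization the analysis model
    uses), and ``eps ~ N(0, ipd_noise_sd^2)``. Dropout and adverse-event flags
    are logistic draws using the ground-truth log odds ratios.
    """
    truth = truth or default_truth()
    if design is None:
        design = default_network_design(n_studies)
    _check_design(design)
    if per_arm_n < 1:
        raise InvalidArgumentError("per_arm_n must be >= 1")
    ae_names = list(ae_names if ae_names is not None else DEFAULT_AE_SUBSET)
    unknown = [a for a in ae_names if a not in truth.log_ors_ae]
    if unknown:
        raise InvalidArgumentError(f"no ground-truth log-ORs for adverse events {unknown}")
    rng = np.random.default_rng(seed)
    tau = float(np.sqrt(truth.tau2))

    frames = []
    for s, arms in enumerate(design):
        b_s = rng.normal(0.0, truth.study_baseline_sd)
        for t in arms:
            df = _draw_covariates(per_arm_n, rng, columns=IPD_COVARIATES)
            df.insert(0, "study_id", f"study_{s + 1:03d}")
            df.insert(1, "treatment", t)
            lp = truth.ipd_intercept + b_s + _centred(df, truth.prognostic_coefficients)
            if t != REFERENCE_EFFICACY:
                u_st = rng.normal(0.0, tau) if tau > 0 else 0.0
                lp = lp + truth.treatment_effects[t] + u_st
                lp = lp + _centred(df, truth.modifier_coefficients)
            df["hdrs_8wk"] = lp + rng.normal(0.0, truth.ipd_noise_sd, per_arm_n)
            p_drop = _expit(_logit(truth.baseline_event_probs["dropout"])
                            + truth.log_ors_dropout[t])
            df["dropout"] = (rng.random(per_arm_n) < p_drop).astype(int)
            ae_cov_lp = _centred(df, truth.ae_covariate_coefficients)
            for ae in ae_names:
                p0 = truth.baseline_event_probs["ae"][ae]
                p_ae = _expit(_logit(p0) + truth.log_ors_ae[ae][t] + ae_cov_lp)
                df[f"ae_{ae}"] = (rng.random(per_arm_n) < p_ae).astype(int)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def generate_ad_network(n_studies: int = 20, per_arm_n: int = 200,
                        truth: TruthParameters | None = None,
                        seed: int = 0,
                        outcome: str = "dropout",
                        design: Sequence[Sequence[str]] | None = None) -> pd.DataFrame:
    """Simulate an aggregate arm-level event network (study, treatment, n, events).

    ``outcome`` is ``"dropout"`` (log odds ratios vs fluoxetine) or the name
    of a configured adverse event (log odds ratios vs paroxetine). Arm event
    probabilities combine a study baseline logit, the treatment's true
    log-OR, and a per-arm heterogeneity draw of variance tau^2 on
    non-reference arms; events are binomial.
    """
    truth = truth or default_truth()
    if outcome == "dropout":
        log_ors = truth.log_ors_dropout
        p0 = truth.baseline_event_probs["dropout"]
        reference = REFERENCE_EFFICACY
    else:
        if outcome not in truth.log_ors_ae:
            raise InvalidArgumentError(f"no ground-truth log-ORs for outcome {outcome!r}")
        log_ors = truth.log_ors_ae[outcome]
        p0 = truth.baseline_event_probs["ae"][outcome]
        reference = REFERENCE_AE
    if design is None:
        design = default_network_design(n_studies)
        if reference != REFERENCE_EFFICACY:
            # re-hub the default design on the outcome's reference drug
            design = [tuple(reference if t == REFERENCE_EFFICACY else
                            (REFERENCE_EFFICACY if t == reference else t) for t in arms)
                      for arms in design]
    _check_design(design)
    if per_arm_n < 1:
        raise InvalidArgumentError("per_arm_n must be >= 1")
    rng = np.random.default_rng(seed)
    tau = float(np.sqrt(truth.tau2))

    rows = []
    for s, arms in enumerate(design):
        alpha_s = _logit(p0) + rng.normal(0.0, 0.3)
        for t in arms:
            lp = alpha_s + log_ors[t]
            if t != reference and tau > 0:
                lp += rng.normal(0.0, tau)
            events = rng.binomial(per_arm_n, _expit(lp))
            rows.append((f"study_{s + 1:03d}", t, per_arm_n, int(events)))
    return pd.DataFrame(rows, columns=["study_id", "treatment", "n", "events"])


def inject_missingness(cohort: pd.DataFrame, mechanism: str = "MCAR",
                       rate: float = 0.3, seed: int = 0,
                       columns: Sequence[str] | None = None,
                       mar_driver: str = "age",
                       mar_slope: float = 1.0) -> pd.DataFrame:
    """Return a copy of ``cohort`` with cells set missing.

    MCAR blanks each eligible cell independently with probability ``rate``.
    MAR makes the per-row missingness probability logistic in the
    standardized ``mar_driver`` (default age) with slope ``mar_slope``, the
    intercept solved so the expected overall rate equals ``rate``. Outcome
    columns and the driver itself are never blanked under the default policy.
    """
    if not 0.0 <= rate < 1.0:
        raise InvalidArgumentError(f"rate must be in [0, 1), got {rate}")
    if mechanism not in ("MCAR", "MAR"):
        raise InvalidArgumentError(f"mechanism must be MCAR or MAR, got {mechanism!r}")
    out = cohort.copy()
    if rate == 0.0:
        return out
    protected = {"patient_id", "study_id", "treatment", *OUTCOME_COLUMNS}
    if columns is None:
        columns = [c for c in out.columns if c not in protected]
    if mechanism == "MAR":
        columns = [c for c in columns if c != mar_driver]
    rng = np.random.default_rng(seed)
    if mechanism == "MCAR":
        p_row = np.full(len(out), rate)
    else:
        z = out[mar_driver].to_numpy(dtype=float)
        z = (z - z.mean()) / (z.std() or 1.0)

        def mean_rate(a: float) -> float:
            return _expit(a + mar_slope * z).mean() - rate

        a = optimize.brentq(mean_rate, -30.0, 30.0)
        p_row = _expit(a + mar_slope * z)
    for c in columns:
        mask = rng.random(len(out)) < p_row
        col = out[c]
        if col.dtype.kind in "iub":  # keep integer flags nullable
            out[c] = col.astype("float64")
        out.loc[mask, c] = np.nan
    return out


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """CSV with a header row; missing values as empty cells."""
    df.to_csv(path, index=False, na_rep="")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
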