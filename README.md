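# petrushka

A personalized antidepressant recommendation engine for adults with major
depressive disorder. Given a patient's baseline covariates and their
preferences about side effects, the engine predicts absolute 8-week outcomes
for 16 antidepressants and returns a ranked top-3 recommendation — the
backend logic of a clinical decision-support tool, packaged as a tested,
reusable Python library.

It is aimed at methodologists and developers of clinical prediction tools:
every stage is an importable function, and synthetic-data generators with
known ground truth make the whole chain verifiable without access to any
proprietary EHR or trial data.

## The model

For each outcome the engine never fits a per-drug model. It combines an
**absolute** prediction on a reference drug with **relative** effects from
network meta-analysis (NMA):

- **Efficacy** (8-week HDRS severity, reference fluoxetine):
  `ŷ(X) = ŷ(fluoxetine) + δ̂(X vs fluoxetine)`,
  where `ŷ(fluoxetine)` comes from EHR-based models (ridge regression with
  restricted cubic splines, a 3×256 MLP, and a stacked meta-learner) fitted
  on the PHQ-9 scale and converted to HDRS through a monotone crosswalk, and
  `δ̂` comes from a one-stage random-effects IPD-NMA with
  treatment-by-covariate interactions, so the relative effect is specific to
  the patient: `δ̂ = d_X + Σ_c γ_c (x_c − x̄_c)`.
- **Acceptability** (all-cause discontinuation) and each **adverse event**:
  `odds(X) = odds(reference) · OR(X vs reference)`, with the absolute
  probability from a ridge logistic model and the odds ratio from an
  aggregate-data NMA (reference paroxetine for adverse events). Adverse
  events enter only if they pass a screening gate: minimum reference-arm
  sample size and cross-validated AUC ≥ 0.55.
- **Recommendation value** (MCDA): efficacy, acceptability and side effects
  each receive weight 0.333; the side-effect mass is split over the ≤5
  adverse events the patient selects (inverse-rank weighted if ranked). Each
  outcome is rescaled by a linear partial value function between the worst
  and best values among the candidate drugs, and the weighted sum in [0, 1]
  ranks the drugs. Clinician exclusions are applied before anchoring.

Missing covariates are handled by multiple imputation with chained additive
regressions (m = 10 by default) and Rubin's rules.

## A worked example

```bash
python examples/04_recommend_patient.py
```

simulates the data sources, fits every model, and recommends for a
47-year-old woman with baseline HDRS 26 who most wants to avoid anxiety and
agitation, with amitriptyline excluded by her clinician. It prints the
full ranking and report; the top of the output looks like:

```
ranking (recommendation value in [0,1]):
  citalopram     0.822  ●●●●○
  sertraline     0.780  ●●●●○
  imipramine     0.611  ●●●○○
  ...
top-3: ['citalopram', 'sertraline', 'imipramine']  (excluded: ['amitriptyline'])

  1. citalopram     ●●●●○  value=0.822  expected HDRS 23.3, stops treatment: 33 in 100
```

A value of 1.0 would mean a drug is best on every weighted criterion for
this patient; dots discretize the value to a 1–5 display strength. The
report shows expected HDRS, the chance of stopping treatment, and each
selected side effect as a natural frequency ("14 in 100"), with a
clinician-only section listing every modeled adverse event.

The other examples demonstrate the pieces: `01_simulate_data.py` (synthetic
EHR cohort, trial IPD, aggregate networks), `02_absolute_models.py` (ridge /
MLP / meta-learner with 10-fold validation), `03_network_meta_analysis.py`
(aggregate and IPD NMA), `05_impute_and_convert.py` (multiple imputation and
PHQ-9↔HDRS conversion). A thin CLI mirrors the library:
`petrushka run --config cfg.json --out artifacts/`.

## Scope

The engine covers the statistical backend only: data simulation, imputation,
score conversion, absolute models, NMAs, prediction combination, and the
preference-weighted ranking. Web deployment, authentication, and trial
conduct around such a tool are out of scope, as is any access to the
proprietary data sources the real system consumes.
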