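# Methods

This note documents the statistical machinery, the choices made where the
design was genuinely open, and what the synthetic test bed does and does not
establish.

## Overview of the pipeline

The engine separates *absolute* from *relative* prediction. Absolute 8-week
outcomes (severity, discontinuation, adverse events) are modeled on a single
reference drug, where observational data are deepest; relative effects
between drugs come from randomized evidence via network meta-analysis, where
confounding by indication is not a concern. The two are fused additively on
the HDRS scale for severity and multiplicatively on the odds scale for
events, and a preference-weighted multiple-criteria layer turns the
per-drug predictions into one recommendation value.

Fluoxetine is the reference for efficacy and discontinuation (largest
primary-care prescribing volume); paroxetine for adverse events (largest
trial arm). Adverse-event predictions are therefore built against
paroxetine throughout and only displayed alongside the fluoxetine-referenced
outcomes; no re-referencing of the absolute probabilities is needed because
the combination acts drug-by-drug.

## Synthetic data generators

Real inputs of this kind — primary-care EHR extracts, pharma trial IPD,
aggregate event networks — are access-controlled, so the package ships
generators whose parameters (`TruthParameters`) are known and serializable.
They emulate:

- **EHR cohort**: independent covariate marginals matched to the trial
  population description (age 44.8 ± 14.2 truncated to 18–74, baseline HDRS
  23.85 ± 3.99, 64.3% female, seven HDRS items with their published means,
  plausible prevalences for history flags, comorbidities and
  co-medications). Truncated-normal locations are solved so the *truncated*
  mean equals the target, keeping moment checks exact. The 8-week severity
  outcome is simulated directly on the PHQ-9 (primary-care records measure
  PHQ-9; conversion happens downstream), as a linear model on centred
  covariates plus Gaussian noise with SD 3 — chosen so a good model's
  cross-validated MAE lands near 2.4 PHQ-9 points, the scale equivalent of
  published cross-validated error for this task. Discontinuation is a
  logistic draw whose covariate effects are sized to a true AUC around
  0.65, in the range published discontinuation models achieve.
- **Trial IPD**: a connected 20-study, 17-node network (16 drugs +
  placebo) with fluoxetine as hub and paroxetine deliberately the
  best-sampled active node, scaled down from the hundreds of trials a real
  corpus holds. Outcomes follow the same mixed model the analysis fits:
  study baseline shifts, treatment effects versus fluoxetine, shared
  treatment-by-covariate interactions, a per-arm random effect with
  variance τ² (drawn only on non-reference arms — the conditional
  parameterization), and residual SD 6 HDRS points.
- **Aggregate networks**: binomial arm counts with study-level baseline
  logits and the same τ² structure on the relative scale.
- **Missingness injection**: MCAR cell-wise, or MAR with a logistic model
  in a driver covariate whose intercept is solved to hit the requested
  overall rate. Outcomes are never blanked under the default policy.

What the generators do *not* emulate: covariate correlation (independent
marginals by default; a Gaussian-copula hook would be the natural
extension), longitudinal visit structure, dosage/duration, EHR coding
systems, and item-total consistency between the HDRS items and the total
score (items are drawn marginally, as they are reported). Passing tests
therefore demonstrate the *statistical machinery* — unbiasedness, coverage,
algebraic identities, determinism — not transportability to real records.

## Multiple imputation

Chained equations with additive (main-effects) imputers: linear for
continuous, logistic/multinomial for categorical, with stochastic draws
(predictive-mean matching optional). m = 10 datasets and 10 sweeps by
default; the outcome is included as a predictor (standard practice, and
exposed as a flag). Integer-valued variables are rounded back onto their
observed grid. Pooling uses Rubin's rules with Barnard–Rubin degrees of
freedom when the complete-data df is supplied. Imputation is performed per
data source, never across sources.

## Crosswalk

A monotone lookup covering the full 0–27 PHQ-9 grid. Forward conversion
interpolates linearly; the reverse is the monotone inverse, returning the
midpoint of the pre-image on flat runs. The bundled table
(`data/crosswalk_synthetic.csv`) is a synthetic stand-in with realistic
shape — published linking tables are not reproduced here — and any table on
the same two-column format can be supplied. Loader validation rejects grid
gaps and non-monotone rows; values above the nominal HDRS maximum are
tolerated (test fixtures use a doubled scale).

## Absolute models

- **Restricted cubic splines**: Harrell's truncated-power basis, k = 4
  knots at the 0.05/0.35/0.65/0.95 quantiles, giving k − 2 nonlinear
  columns plus the linear term, exactly linear beyond the boundary knots.
- **Ridge**: predictors standardized internally, intercept unpenalized;
  λ = 0 reproduces OLS / plain logistic to numerical precision; λ chosen by
  inner 5-fold cross-validation (log-loss for the binary family) when not
  fixed.
- **MLP**: three hidden layers of 256 ReLU units by default, Adam, early
  stopping with patience 10 on a 10% validation split, targets standardized
  internally; deterministic under seed.
- **Meta-learner**: an MLP stacked on *out-of-fold* base predictions
  (leak-free), optionally alongside covariates (flag, off by default since
  nothing fixes this choice); base models are refit on the full data for
  deployment.
- **Validation**: k = 10 folds (stratified for binary outcomes), MAE for
  continuous models; AUC and calibration slope (GLM of the outcome on the
  logit of predicted risk) on pooled out-of-fold predictions for binary
  models. Ten folds and MAE are the conventional choices for internal
  validation of clinical prediction models and are used throughout.
- **Screening**: an adverse event enters only if the reference arm reaches
  the minimum sample size for a reliable risk model — the maximum of an
  events-per-parameter rule (10 × parameters / prevalence) and a
  shrinkage-based rule (parameters / ((S−1)·ln(1−R²_cs/S)), S = 0.9) — and
  its model's cross-validated AUC is ≥ 0.55, inclusive at the boundary. All
  rule parameters sit in `ScreenConfig`; the pipeline defaults the
  parameter count to the fitted design size and the anticipated Cox–Snell
  R² to 0.15 for these deliberately lean adverse-event models.
- Predictions are clamped post hoc to displayable ranges (HDRS 0–52,
  probabilities inside (10⁻⁶, 1−10⁻⁶)) — decision-aid outputs must be
  finite and on-scale.

## Network meta-analysis

- **Pairwise**: inverse-variance pooling with the DerSimonian–Laird moment
  τ².
- **Aggregate NMA**: contrast-based. Per-study log odds ratios against the
  study's first arm, with a 0.5 continuity correction applied to every cell
  of a study containing a zero (or full) arm and zero-information studies
  dropped. Weighted GLS over the network design with the within-study
  covariance of shared-baseline contrasts; a multivariate moment τ²
  (random-effect structure matrix with 0.5 off-diagonals inside multi-arm
  studies) generalizing DerSimonian–Laird — on a two-treatment network it
  reduces to pairwise pooling exactly, which the tests assert to 1e-8.
  Estimates re-express against any reference; contrasts between
  non-reference drugs are invariant to that choice (1e-10).
- **IPD-NMA (one-stage)**: linear mixed model with fixed study intercepts,
  fixed treatment effects versus the reference, covariate main effects,
  and treatment-by-covariate interactions, estimated by REML. Interactions
  are shared across non-reference arms by default (parsimony; drug-specific
  mode behind a flag). The study-by-treatment random effect is a single
  variance component on non-reference-arm indicators (τ²). Covariates are
  centred at the network mean, so main effects are the relative effects for
  the average participant and `predict_delta` is a linear predictor with a
  delta-method SE. Covariate main effects are included so interactions are
  not confounded with prognosis.
- With 1–3 trials per comparison the moment and REML τ̂² often hit zero,
  and intervals understate heterogeneity — visible in the examples and
  inherent to small networks, not an implementation artifact. Recovery
  tests instead assert what small networks *can* deliver: treatment-effect
  bias below 0.1 HDRS points and 90–98% coverage over 100 replicates at 20
  studies × 200/arm.

## Combination and MCDA

The odds-scale combination `p = σ(logit(p_ref) + log OR)` satisfies exact
identity, inverse and composition laws (asserted to 1e-12); the HDRS
combination is additive with clamping. For the reference drug the combined
value *is* the absolute model output.

MCDA: equal thirds (0.333) for efficacy, acceptability and side effects;
the side-effect mass splits equally over the selected events, proportional
to inverse rank when ranked (1, 1/2, 1/3, … renormalized — a simple,
monotone mapping; nothing in the source design fixes the rank rule), or
over all modeled events on opt-out. Partial value functions are linear
between per-patient worst/best anchors across the candidate drugs ("local"
anchoring — maximal discrimination among the actual options; global
clinical anchors available via `anchors="global"`). Exclusions are applied
before anchors so an excluded drug cannot distort the scale. Ties break by
better efficacy, then lower discontinuation, then name. Dot strength is
`1 + round(4·value)`, mapping 0→1 dot and 1→5 dots. When no adverse event
survives screening, the side-effect mass is dropped and the remaining two
criteria are renormalized.

## Pipeline, determinism, problem sizes

`run_pipeline` fans a single seed out deterministically to every stage and
writes sorted-key JSON artifacts with SHA-256 hashes in a manifest;
rerunning a config is byte-identical. Per-imputation model fits are
combined by averaging predictions (pooling the quantity the decision aid
consumes). Drugs not covered by the simulated network are dropped from the
candidate list with a warning. The default demonstration sizes — 2,000 EHR
records, 20 trials of 200–250 per arm, 100-replicate recovery studies —
are the package's desk-scale choices: large enough for the Monte-Carlo
tolerances used in the tests (3 SE), small enough to iterate on. The same
code paths scale to production sizes unchanged.

## Known limitations

- Uncertainty in combined per-drug predictions is propagated by the delta
  method internally but not surfaced in the default report, which shows
  point predictions only.
- Outcomes are treated as independent in the MCDA layer; no joint model of
  severity, dropout and adverse events.
- The bundled crosswalk is synthetic; deployments must supply a published
  linking table.
- The one-stage IPD-NMA assumes a common interaction per covariate across
  drugs by default and a single τ² across comparisons.
- The screening gate's sample-size rules use anticipated-performance
  parameters that must be set honestly per application; the defaults are
  documented, not universal.
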