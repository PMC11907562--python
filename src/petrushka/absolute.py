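"""Reference-drug absolute-outcome models.

For a patient on the reference drug, these models predict the absolute
outcome: 8-week severity (continuous, ridge linear regression with
restricted-cubic-spline expansions of continuous predictors, an MLP, and a
stacked meta-learner combining them) and binary events (all-cause
discontinuation, each adverse event) via ridge logistic regression.

All fits standardize predictors internally and leave the intercept
unpenalized; the regularization strength ``lam`` corresponds to an L2
penalty ``lam * ||beta||^2 / 2`` on standardized coefficients and is chosen
by inner cross-validation when not supplied. Internal validation is k-fold
(default 10) reporting the mean absolute error for continuous models, and
the AUC plus calibration slope (slope of the outcome on the logit of
predicted risk; 1.0 = well calibrated) for binary models.

Adverse-event models pass a screening gate before entering the decision aid:
the reference-arm sample must reach the minimum size required for a reliable
risk model (events-per-parameter and expected-shrinkage criteria), and the
cross-validated AUC must be at least 0.55.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, Ridge, RidgeCV
from sklearn.metrics import log_loss
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier, MLPRegressor

from .errors import (
    DataError,
    DegenerateOutcomeError,
    InvalidArgumentError,
)
from .splines import SplineBasis, build_spline_basis
from .treatments import ADVERSE_EVENTS, REFERENCE_AE, REFERENCE_EFFICACY

__all__ = [
    "ModelSpec", "AbsoluteModel", "ValidationReport", "ScreenConfig",
    "AEScreenResult", "build_design", "fit_ridge", "fit_mlp",
    "fit_meta_learner", "fit_model", "cross_validate", "screen_adverse_events",
    "minimum_sample_size",
]

_LAMBDA_GRID = np.logspace(-3, 3, 13)

CLIP_EPS = 1e-6  # probabilities kept inside (eps, 1-eps)


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


@dataclass
class DesignInfo:
    """Mapping from a raw covariate table to the numeric design matrix."""

    continuous: list[str]
    passthrough: list[str]
    spline_bases: dict[str, SplineBasis]
    feature_names: list[str]

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        blocks = []
        for c in self.continuous:
            x = df[c].to_numpy(dtype=float)
            basis = self.spline_bases.get(c)
            blocks.append(basis.design(x) if basis is not None else x[:, None])
        for c in self.passthrough:
            blocks.append(df[c].to_numpy(dtype=float)[:, None])
        return np.column_stack(blocks) if blocks else np.empty((len(df), 0))


def build_design(df: pd.DataFrame, continuous: Sequence[str],
                 passthrough: Sequence[str], spline: bool = True,
                 n_knots: int = 4) -> tuple[np.ndarray, DesignInfo]:
    """Expand continuous predictors with restricted cubic splines (4 knots)."""
    bases: dict[str, SplineBasis] = {}
    names: list[str] = []
    for c in continuous:
        if spline:
            try:
                bases[c] = build_spline_basis(df[c].to_numpy(dtype=float), n_knots)
                names += [c] + [f"{c}_rcs{j + 1}" for j in range(bases[c].n_nonlinear)]
                continue
            except Exception:
                pass  # too few distinct values: keep the linear term only
        names.append(c)
    names += list(passthrough)
    info = DesignInfo(continuous=list(continuous), passthrough=list(passthrough),
                      spline_bases=bases, feature_names=names)
    return info.transform(df), info


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """Recipe for a fit, so folds and stacks can refit from scratch."""

    kind: str                      # "ridge" | "mlp" | "stack"
    family: str                    # "continuous" | "binary"
    params: dict = field(default_factory=dict)


@dataclass
class AbsoluteModel:
    """A fitted absolute-outcome model for the reference drug."""

    family: str
    kind: str
    estimator: object
    x_mean: np.ndarray
    x_sd: np.ndarray
    feature_names: list[str] | None = None
    reference_drug: str = REFERENCE_EFFICACY
    bounds: tuple[float, float] | None = None
    lambda_: float | None = None
    base_models: list["AbsoluteModel"] | None = None
    include_covariates: bool = False
    spec: ModelSpec | None = None
    y_mean: float = 0.0  # target standardization (MLP / stack, continuous)
    y_sd: float = 1.0

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.x_mean) / self.x_sd

    def predict(self, X, clip: bool = True) -> np.ndarray:
        """Predicted outcome (continuous) or event probability (binary)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.kind == "stack":
            feats = np.column_stack([m.predict(X, clip=False) for m in self.base_models])
            if self.include_covariates:
                feats = np.column_stack([feats, self._standardize(X)])
            inner = self.estimator
            out = (inner.predict_proba(feats)[:, 1] if self.family == "binary"
                   else inner.predict(feats))
        else:
            Z = self._standardize(X)
            out = (self.estimator.predict_proba(Z)[:, 1] if self.family == "binary"
                   else self.estimator.predict(Z))
        out = np.asarray(out, dtype=float)
        if self.family == "continuous" and self.kind in ("mlp", "stack"):
            out = out * self.y_sd + self.y_mean
        if clip:
            if self.family == "binary":
                out = np.clip(out, CLIP_EPS, 1.0 - CLIP_EPS)
            elif self.bounds is not None:
                out = np.clip(out, *self.bounds)
        return out

    def coefficients_original(self) -> tuple[float, np.ndarray]:
        """(intercept, coefficients) mapped back to the raw predictor scale."""
        if self.kind not in ("ridge",):
            raise InvalidArgumentError("only ridge models expose linear coefficients")
        coef = np.ravel(self.estimator.coef_)
        inter = float(np.ravel(self.estimator.intercept_)[0]) \
            if np.ndim(self.estimator.intercept_) else float(self.estimator.intercept_)
        b = coef / self.x_sd
        return inter - float(np.sum(coef * self.x_mean / self.x_sd)), b

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize coefficients/weights and preprocessing with a version tag."""
        payload: dict = {
            "format_version": 1, "family": self.family, "kind": self.kind,
            "reference_drug": self.reference_drug, "bounds": self.bounds,
            "lambda": self.lambda_, "feature_names": self.feature_names,
            "x_mean": self.x_mean.tolist(), "x_sd": self.x_sd.tolist(),
        }
        est = self.estimator
        if self.kind == "ridge":
            payload["coef"] = np.ravel(est.coef_).tolist()
            payload["intercept"] = float(np.ravel(est.intercept_)[0]) \
                if np.ndim(est.intercept_) else float(est.intercept_)
        elif hasattr(est, "coefs_"):
            payload["weights"] = [w.tolist() for w in est.coefs_]
            payload["biases"] = [b.tolist() for b in est.intercepts_]
        text = json.dumps(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _prep(X, y):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise DataError("non-finite values in model inputs")
    if np.isnan(X).any() or np.isnan(y).any():
        raise DataError("missing cells in model inputs; impute first")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return X, y, mean, sd


def _select_lambda_binary(Z: np.ndarray, y: np.ndarray, seed: int) -> float:
    """Pick the ridge penalty by 5-fold cross-validated log-loss."""
    folds = list(StratifiedKFold(n_splits=5, shuffle=True, random_state=seed).split(Z, y))
    best_lam, best_loss = 1.0, np.inf
    for lam in _LAMBDA_GRID:
        losses = []
        for tr, va in folds:
            m = LogisticRegression(C=1.0 / lam, max_iter=2000).fit(Z[tr], y[tr])
            losses.append(log_loss(y[va], m.predict_proba(Z[va])[:, 1], labels=[0, 1]))
        loss = float(np.mean(losses))
        if loss < best_loss:
            best_lam, best_loss = float(lam), loss
    return best_lam


def fit_ridge(X, y, family: str = "continuous", lam: float | None = None,
              feature_names: Sequence[str] | None = None,
              bounds: tuple[float, float] | None = None,
              seed: int = 0) -> AbsoluteModel:
    """Ridge fit with standardized predictors and an unpenalized intercept.

    ``lam`` is the L2 penalty on standardized coefficients; ``lam=0`` is the
    unpenalized (OLS / plain logistic) fit, ``lam=None`` selects it by inner
    5-fold cross-validation on a log-spaced grid.
    """
    if lam is not None and lam < 0:
        raise InvalidArgumentError("lambda must be >= 0")
    X, y, mean, sd = _prep(X, y)
    Z = (X - mean) / sd
    if family == "continuous":
        if lam is None:
            cv = RidgeCV(alphas=_LAMBDA_GRID).fit(Z, y)
            lam = float(cv.alpha_)
        est = Ridge(alpha=lam, solver="svd").fit(Z, y)
    elif family == "binary":
        if len(np.unique(y)) < 2:
            raise DegenerateOutcomeError("binary outcome is constant")
        if lam is None:
            lam = _select_lambda_binary(Z, y, seed)
        if lam == 0:
            est = LogisticRegression(penalty=None, max_iter=5000).fit(Z, y)
        else:
            est = LogisticRegression(C=1.0 / lam, max_iter=5000).fit(Z, y)
    else:
        raise InvalidArgumentError(f"unknown family {family!r}")
    return AbsoluteModel(family=family, kind="ridge", estimator=est, x_mean=mean,
                         x_sd=sd, feature_names=list(feature_names) if feature_names else None,
                         bounds=bounds, lambda_=lam,
                         spec=ModelSpec("ridge", family, {"lam": lam}))


def fit_mlp(X, y, family: str = "continuous", seed: int = 0,
            hidden: tuple[int, ...] = (256, 256, 256),
            bounds: tuple[float, float] | None = None,
            max_iter: int = 300, patience: int = 10) -> AbsoluteModel:
    """Multi-layer perceptron (default three hidden layers of 256 units).

    ReLU activations, Adam optimizer, early stopping on a 10% validation
    split with the given patience; deterministic under ``seed``.
    """
    X, y, mean, sd = _prep(X, y)
    Z = (X - mean) / sd
    common = dict(hidden_layer_sizes=hidden, activation="relu", solver="adam",
                  early_stopping=True, n_iter_no_change=patience,
                  validation_fraction=0.1, max_iter=max_iter, random_state=seed)
    y_mean, y_sd = 0.0, 1.0
    if family == "continuous":
        y_mean = float(y.mean())
        y_sd = float(y.std()) or 1.0
        est = MLPRegressor(**common).fit(Z, (y - y_mean) / y_sd)
    elif family == "binary":
        if len(np.unique(y)) < 2:
            raise DegenerateOutcomeError("binary outcome is constant")
        est = MLPClassifier(**common).fit(Z, y.astype(int))
    else:
        raise InvalidArgumentError(f"unknown family {family!r}")
    return AbsoluteModel(family=family, kind="mlp", estimator=est, x_mean=mean,
                         x_sd=sd, bounds=bounds, y_mean=y_mean, y_sd=y_sd,
                         spec=ModelSpec("mlp", family,
                                        {"hidden": hidden, "max_iter": max_iter,
                                         "patience": patience, "seed": seed}))


def fit_model(spec: ModelSpec, X, y, seed: int = 0,
              bounds: tuple[float, float] | None = None) -> AbsoluteModel:
    """Fit any :class:`ModelSpec` (dispatch used by CV folds and stacking)."""
    if spec.kind == "ridge":
        return fit_ridge(X, y, family=spec.family, bounds=bounds, seed=seed,
                         **{k: v for k, v in spec.params.items() if k == "lam"})
    if spec.kind == "mlp":
        p = dict(spec.params)
        p.setdefault("seed", seed)
        return fit_mlp(X, y, family=spec.family, bounds=bounds, **p)
    if spec.kind == "stack":
        p = dict(spec.params)
        base = [ModelSpec(**b) if isinstance(b, dict) else b for b in p.pop("base", [])]
        return fit_meta_learner(base, X, y, seed=p.pop("seed", seed),
                                bounds=bounds, **p)
    raise InvalidArgumentError(f"unknown model kind {spec.kind!r}")


def fit_meta_learner(base: Sequence[ModelSpec | AbsoluteModel], X, y,
                     seed: int = 0, n_folds: int = 5,
                     include_covariates: bool = False,
                     hidden: tuple[int, ...] = (64, 64),
                     bounds: tuple[float, float] | None = None) -> AbsoluteModel:
    """Stacked meta-learner over base models.

    The meta model (an MLP) is trained on out-of-fold predictions of the base
    models — never on in-fold predictions, which would leak the outcome —
    optionally alongside the standardized covariates. The base models are
    then refit on the full data for deployment.
    """
    specs = [b.spec if isinstance(b, AbsoluteModel) else b for b in base]
    if len(specs) < 2:
        raise InvalidArgumentError("stacking needs >= 2 base models")
    families = {s.family for s in specs}
    if len(families) != 1:
        raise InvalidArgumentError(f"base models must share a family, got {families}")
    family = families.pop()
    X, y, mean, sd = _prep(X, y)
    n = len(y)
    if family == "binary":
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(X, y)
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(X)
    oof = np.zeros((n, len(specs)))
    for tr, va in split_iter:
        for j, s in enumerate(specs):
            m = fit_model(s, X[tr], y[tr], seed=seed)
            oof[va, j] = m.predict(X[va], clip=False)
    feats = oof if not include_covariates else np.column_stack([oof, (X - mean) / sd])
    common = dict(hidden_layer_sizes=hidden, activation="relu", solver="adam",
                  early_stopping=True, n_iter_no_change=10,
                  validation_fraction=0.1, max_iter=500, random_state=seed)
    y_mean, y_sd = 0.0, 1.0
    if family == "binary":
        meta = MLPClassifier(**common).fit(feats, y.astype(int))
    else:
        y_mean = float(y.mean())
        y_sd = float(y.std()) or 1.0
        meta = MLPRegressor(**common).fit(feats, (y - y_mean) / y_sd)
    full_base = [fit_model(s, X, y, seed=seed) for s in specs]
    return AbsoluteModel(
        family=family, kind="stack", estimator=meta, x_mean=mean, x_sd=sd,
        bounds=bounds, base_models=full_base, include_covariates=include_covariates,
        y_mean=y_mean, y_sd=y_sd,
        spec=ModelSpec("stack", family,
                       {"base": [asdict(s) for s in specs], "n_folds": n_folds,
                        "include_covariates": include_covariates,
                        "hidden": hidden, "seed": seed}))


# ---------------------------------------------------------------------------
# Internal validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """k-fold internal validation summary."""

    k: int
    family: str
    mae: float | None = None                # continuous
    auc: float | None = None                # binary, pooled out-of-fold
    calibration_slope: float | None = None  # binary, pooled out-of-fold
    per_fold: dict[str, list[float]] = field(default_factory=dict)


def _logit(p):
    p = np.clip(p, CLIP_EPS, 1 - CLIP_EPS)
    return np.log(p / (1 - p))


def calibration_slope(y, p) -> float:
    """Slope of the outcome on the logit of predicted risk (1.0 = calibrated)."""
    import statsmodels.api as sm

    lp = _logit(np.asarray(p, dtype=float))
    model = sm.GLM(np.asarray(y, dtype=float), sm.add_constant(lp),
                   family=sm.families.Binomial())
    return float(model.fit().params[1])


def cross_validate(spec: ModelSpec, X, y, k: int = 10, seed: int = 0) -> ValidationReport:
    """k-fold cross-validation with deterministic fold assignment.

    Continuous models report the mean absolute error; binary models report
    the AUC and the calibration slope, computed on the pooled out-of-fold
    predictions (per-fold values are kept alongside).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if k < 2 or k > n:
        raise InvalidArgumentError(f"need 2 <= k <= n, got k={k}, n={n}")
    binary = spec.family == "binary"
    splitter = (StratifiedKFold(n_splits=k, shuffle=True, random_state=seed) if binary
                else KFold(n_splits=k, shuffle=True, random_state=seed))
    oof = np.full(n, np.nan)
    per_fold: dict[str, list[float]] = {"mae": [], "auc": []}
    for tr, va in splitter.split(X, y if binary else None):
        m = fit_model(spec, X[tr], y[tr], seed=seed)
        p = m.predict(X[va])
        oof[va] = p
        if binary:
            if len(np.unique(y[va])) > 1:
                per_fold["auc"].append(float(roc_auc_score(y[va], p)))
        else:
            per_fold["mae"].append(float(np.mean(np.abs(y[va] - p))))
    if binary:
        return ValidationReport(
            k=k, family=spec.family,
            auc=float(roc_auc_score(y, oof)),
            calibration_slope=calibration_slope(y, oof),
            per_fold={"auc": per_fold["auc"]})
    return ValidationReport(k=k, family=spec.family,
                            mae=float(np.mean(np.abs(y - oof))),
                            per_fold={"mae": per_fold["mae"]})


# ---------------------------------------------------------------------------
# Adverse-event screening
# ---------------------------------------------------------------------------


@dataclass
class ScreenConfig:
    """Minimum-sample-size rules for adverse-event risk models.

    ``min_n = max(events-per-parameter rule, shrinkage rule)`` with
    ``n_epp = epp * n_params / prevalence`` and
    ``n_shrink = n_params / ((shrinkage - 1) * ln(1 - r2_cs / shrinkage))``.
    """

    n_params: int = 20          # candidate model parameters
    epp: float = 10.0           # events per candidate parameter
    shrinkage: float = 0.9      # targeted expected shrinkage factor
    r2_cs: float = 0.05         # anticipated Cox-Snell R^2
    auc_threshold: float = 0.55  # exclusion below this AUC (inclusive at 0.55)


def minimum_sample_size(prevalence: float, config: ScreenConfig) -> float:
    """Minimum reference-arm n for a reliable risk model of a binary event."""
    if not 0 < prevalence < 1:
        raise InvalidArgumentError("prevalence must be in (0,1)")
    n_epp = config.epp * config.n_params / prevalence
    n_shrink = config.n_params / ((config.shrinkage - 1.0)
                                  * np.log(1.0 - config.r2_cs / config.shrinkage))
    return float(max(n_epp, n_shrink))


@dataclass
class AEScreenResult:
    """Outcome of the adverse-event screen; ``table`` has one row per AE."""

    table: pd.DataFrame  # columns: ae, n_available, prevalence, min_n_required, auc, included

    @property
    def included(self) -> list[str]:
        return self.table.loc[self.table["included"], "ae"].tolist()


def screen_adverse_events(ipd: pd.DataFrame | None,
                          validation: Mapping[str, "ValidationReport | float"],
                          reference_arm: str = REFERENCE_AE,
                          n_available: Mapping[str, int] | None = None,
                          prevalence: Mapping[str, float] | None = None,
                          config: ScreenConfig | None = None) -> AEScreenResult:
    """Apply the two-stage adverse-event screen.

    An event enters the decision aid only if (a) the reference arm provides
    at least the minimum sample size its prevalence requires and (b) the
    cross-validated AUC of its risk model is at least the threshold
    (inclusive at the boundary). ``n_available`` and ``prevalence`` are
    counted from ``ipd`` (rows of the reference arm with a non-missing
    ``ae_<name>`` flag) when not supplied directly.
    """
    config = config or ScreenConfig()
    names = list(validation)
    for ae in names:
        if ae not in ADVERSE_EVENTS:
            raise InvalidArgumentError(f"unknown adverse event {ae!r}")
    n_avail: dict[str, int] = dict(n_available or {})
    prev: dict[str, float] = dict(prevalence or {})
    if ipd is not None:
        ref = ipd[ipd["treatment"] == reference_arm]
        for ae in names:
            col = f"ae_{ae}"
            if col not in ipd.columns:
                raise InvalidArgumentError(f"IPD has no column {col!r}")
            obs = ref[col].dropna()
            n_avail.setdefault(ae, int(len(obs)))
            if len(obs):
                prev.setdefault(ae, float(np.clip(obs.mean(), 1e-3, 1 - 1e-3)))
    rows = []
    for ae in names:
        v = validation[ae]
        auc = v.auc if isinstance(v, ValidationReport) else float(v)
        n = n_avail.get(ae, 0)
        phi = prev.get(ae, 0.1)
        min_n = minimum_sample_size(phi, config)
        included = (n >= min_n) and (auc >= config.auc_threshold)
        rows.append((ae, n, phi, min_n, auc, included))
    table = pd.DataFrame(rows, columns=["ae", "n_available", "prevalence",
                                        "min_n_required", "auc", "included"])
    return AEScreenResult(table=table)
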