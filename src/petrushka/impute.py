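"""Multiple imputation by chained additive regressions, and Rubin pooling.

Each incomplete variable is regressed on all others with a main-effects
(additive) model — linear for continuous, logistic for binary, multinomial
for categorical — and missing entries are replaced by stochastic draws from
the fitted model. Sweeping over the variables a fixed number of times yields
one completed dataset; m independent chains yield m. Downstream estimates
computed on each completed dataset are pooled with Rubin's rules, with the
Barnard-Rubin small-sample degrees of freedom when the complete-data degrees
of freedom are supplied.

Predictive-mean matching is available as an option (draws are then observed
values whose fitted means are closest to the fitted mean of the missing
entry) but stochastic regression draws are the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression, LogisticRegression

from .errors import InvalidArgumentError, UnimputableVariableError

__all__ = ["ImputedSets", "PooledEstimate", "impute_multiple", "pool_estimates"]


@dataclass
class ImputedSets:
    """m completed datasets plus per-variable imputation-model summaries."""

    m: int
    datasets: list[pd.DataFrame]
    model_summaries: dict[str, dict] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.datasets)


@dataclass
class PooledEstimate:
    """Rubin-rule combination of one estimate across imputed datasets."""

    estimate: float
    within_variance: float
    between_variance: float
    total_variance: float
    degrees_of_freedom: float

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_variance))


def _classify(col: pd.Series) -> str:
    """continuous / binary / categorical, judged on observed values."""
    obs = col.dropna()
    if obs.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        return "binary" if obs.nunique() == 2 else "categorical"
    uniq = obs.unique()
    if len(uniq) <= 2 and set(np.asarray(uniq, dtype=float)) <= {0.0, 1.0}:
        return "binary"
    return "continuous"


def _design(df: pd.DataFrame, predictors: Sequence[str]) -> np.ndarray:
    """Numeric main-effects design: one-hot for object/category columns."""
    blocks = []
    for c in predictors:
        col = df[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=c, drop_first=True)
            blocks.append(dummies.to_numpy(dtype=float))
        else:
            blocks.append(col.to_numpy(dtype=float)[:, None])
    if not blocks:
        return np.ones((len(df), 1))
    X = np.column_stack(blocks)
    # drop constant columns and standardize: stabilizes the solvers
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():
        return np.ones((len(df), 1))
    X = X[:, keep]
    return (X - X.mean(axis=0)) / X.std(axis=0)


def _is_integer_valued(col: pd.Series) -> bool:
    """Whether the observed values are all integers (scores stay on-grid)."""
    if col.dtype.kind in "iu":
        return True
    if col.dtype.kind == "f":
        obs = col.dropna().to_numpy()
        return len(obs) > 0 and bool(np.all(obs == np.rint(obs)))
    return False


def _pmm_draw(fitted_obs: np.ndarray, y_obs: np.ndarray, fitted_mis: np.ndarray,
              rng: np.random.Generator, k: int = 5) -> np.ndarray:
    """Predictive-mean matching: draw among the k observed nearest fits."""
    out = np.empty(len(fitted_mis))
    order = np.argsort(fitted_obs)
    sorted_fits = fitted_obs[order]
    for i, f in enumerate(fitted_mis):
        pos = np.searchsorted(sorted_fits, f)
        lo = max(0, pos - k)
        hi = min(len(sorted_fits), pos + k)
        cand = order[lo:hi]
        dist = np.abs(fitted_obs[cand] - f)
        donors = cand[np.argsort(dist)[:k]]
        out[i] = y_obs[donors[rng.integers(len(donors))]]
    return out


def impute_multiple(data: pd.DataFrame, m: int = 10, seed: int = 0,
                    sweeps: int = 10, method: str = "regression",
                    include_outcome: bool = True,
                    exclude: Sequence[str] = ()) -> ImputedSets:
    """Chained-equation multiple imputation of a cohort or trial table.

    Parameters
    ----------
    data : table with missing cells (NaN / empty).
    m : number of completed datasets (default 10).
    sweeps : chained-equation passes over the incomplete variables per chain.
    method : ``"regression"`` (stochastic regression draws, default) or
        ``"pmm"`` (predictive-mean matching) for continuous variables.
    include_outcome : include outcome columns as predictors in the
        imputation models (standard practice; set False to drop them).
    exclude : columns never used as predictors nor imputed (identifiers).

    Observed cells are identical across all m datasets; a variable that is
    100% missing raises :class:`UnimputableVariableError`.
    """
    if m < 1:
        raise InvalidArgumentError(f"m must be >= 1, got {m}")
    if method not in ("regression", "pmm"):
        raise InvalidArgumentError(f"unknown method {method!r}")
    from .synthetic import OUTCOME_COLUMNS  # local import avoids a cycle

    work_cols = [c for c in data.columns if c not in exclude]
    if not include_outcome:
        work_cols = [c for c in work_cols if c not in OUTCOME_COLUMNS]

    fully_missing = [c for c in work_cols if data[c].isna().all()]
    if fully_missing:
        raise UnimputableVariableError(
            f"variables with 100% missingness cannot be imputed: {fully_missing}")
    if not any(data[c].notna().all() for c in work_cols):
        raise InvalidArgumentError("need at least one fully observed variable")

    incomplete = [c for c in work_cols if data[c].isna().any()]
    if not incomplete:
        return ImputedSets(m=m, datasets=[data.copy() for _ in range(m)])

    # visit in order of increasing missingness (stabler chains)
    incomplete.sort(key=lambda c: data[c].isna().sum())
    kinds = {c: _classify(data[c]) for c in incomplete}
    summaries: dict[str, dict] = {
        c: {"kind": kinds[c], "n_missing": int(data[c].isna().sum())} for c in incomplete
    }

    rng = np.random.default_rng(seed)
    datasets = []
    for _ in range(m):
        datasets.append(_impute_once(data, work_cols, incomplete, kinds,
                                     sweeps, method, rng))
    return ImputedSets(m=m, datasets=datasets, model_summaries=summaries)


def _impute_once(data: pd.DataFrame, work_cols: list[str], incomplete: list[str],
                 kinds: dict[str, str], sweeps: int, method: str,
                 rng: np.random.Generator) -> pd.DataFrame:
    df = data.copy()
    masks = {c: data[c].isna().to_numpy() for c in incomplete}
    # initial fill: bootstrap draws from each variable's observed values
    for c in incomplete:
        obs = data[c].dropna().to_numpy()
        df.loc[masks[c], c] = rng.choice(obs, size=int(masks[c].sum()), replace=True)

    for _ in range(max(1, sweeps)):
        for c in incomplete:
            mask = masks[c]
            predictors = [p for p in work_cols if p != c]
            X = _design(df, predictors)
            X_obs, X_mis = X[~mask], X[mask]
            y_obs = data.loc[~mask, c]
            kind = kinds[c]
            if kind == "continuous":
                reg = LinearRegression().fit(X_obs, y_obs.to_numpy(dtype=float))
                fit_obs = reg.predict(X_obs)
                resid = y_obs.to_numpy(dtype=float) - fit_obs
                dof = max(1, len(y_obs) - X_obs.shape[1] - 1)
                sigma = float(np.sqrt((resid ** 2).sum() / dof))
                fit_mis = reg.predict(X_mis)
                if method == "pmm":
                    draws = _pmm_draw(fit_obs, y_obs.to_numpy(dtype=float), fit_mis, rng)
                else:
                    draws = fit_mis + rng.normal(0.0, sigma, len(fit_mis))
                if _is_integer_valued(data[c]):
                    lo, hi = data[c].min(), data[c].max()
                    draws = np.clip(np.rint(draws), lo, hi)
                df.loc[mask, c] = draws
            else:
                codes, levels = pd.factorize(y_obs)
                if len(levels) < 2:  # no variation among observed: carry the mode
                    df.loc[mask, c] = levels[0]
                    continue
                clf = LogisticRegression(max_iter=1000).fit(X_obs, codes)
                probs = clf.predict_proba(X_mis)
                cum = probs.cumsum(axis=1)
                u = rng.random(len(X_mis))[:, None]
                idx = (u > cum).sum(axis=1)
                df.loc[mask, c] = np.asarray(levels)[idx]
    for c in incomplete:  # restore integer dtypes where the source was integer
        if data[c].dtype.kind in "iu":
            df[c] = df[c].astype(data[c].dtype)
    return df


def pool_estimates(per_dataset: Sequence[tuple[float, float]],
                   complete_data_df: float | None = None) -> PooledEstimate:
    """Combine per-dataset (estimate, variance) pairs with Rubin's rules.

    The pooled point estimate is the mean of the per-dataset estimates; the
    total variance is ``W + (1 + 1/m) B`` where W is the mean within-dataset
    variance and B the between-dataset variance. Degrees of freedom follow
    Barnard-Rubin when ``complete_data_df`` is given, otherwise the classical
    large-sample formula.
    """
    per_dataset = list(per_dataset)
    if not per_dataset:
        raise InvalidArgumentError("pool_estimates needs at least one entry")
    ests = np.array([e for e, _ in per_dataset], dtype=float)
    vars_ = np.array([v for _, v in per_dataset], dtype=float)
    if (vars_ < 0).any():
        raise InvalidArgumentError("variances must be >= 0")
    m = len(ests)
    qbar = float(ests.mean())
    W = float(vars_.mean())
    B = float(ests.var(ddof=1)) if m > 1 else 0.0
    T = W + (1.0 + 1.0 / m) * B
    if B == 0.0 or m == 1:
        df = float("inf")
    else:
        r = (1.0 + 1.0 / m) * B
        df = (m - 1) * (1.0 + W / r) ** 2
        if complete_data_df is not None and np.isfinite(complete_data_df):
            lam = r / T
            nu_com = float(complete_data_df)
            nu_obs = (nu_com + 1.0) / (nu_com + 3.0) * nu_com * (1.0 - lam)
            df = 1.0 / (1.0 / df + 1.0 / nu_obs)
    return PooledEstimate(estimate=qbar, within_variance=W, between_variance=B,
                          total_variance=T, degrees_of_freedom=df)
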