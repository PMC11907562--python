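"""Random-effects network meta-analysis.

Three layers, each feeding the next:

* :func:`pairwise_ma` — classical inverse-variance pooling of study effects
  with the DerSimonian-Laird moment estimator of the between-study variance
  tau^2 (the two-treatment building block).
* :func:`fit_ad_nma` — contrast-based NMA of an aggregate arm-level event
  network on the log odds ratio scale: per-study contrasts against the
  study's first arm (0.5 continuity correction on affected tables),
  weighted generalized least squares over the network design, a
  multivariate moment tau^2 (random-effect structure with 0.5 correlation
  between contrasts of multi-arm trials), and re-expression against any
  reference drug.
* :func:`fit_ipd_nma` — one-stage linear mixed model on trial IPD: fixed
  study intercepts, fixed treatment effects versus the reference,
  covariate main effects and treatment-by-covariate interactions (shared
  across non-reference arms by default), and a study-by-treatment random
  effect with common variance tau^2 (REML). Its
  :meth:`ModifierModel.predict_delta` yields a patient-specific relative
  effect with a delta-method standard error.

Covariates are centred at the network mean, so each treatment main effect
is the relative effect for the average trial participant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import IdentifiabilityError, InvalidArgumentError, NetworkError

__all__ = ["PairwiseResult", "RelativeEffects", "ModifierModel",
           "pairwise_ma", "fit_ad_nma", "fit_ipd_nma", "predict_delta"]


# ---------------------------------------------------------------------------
# Pairwise building block
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairwiseResult:
    pooled: float
    se: float
    tau2: float
    q: float
    k: int


def pairwise_ma(studies: Sequence[tuple[float, float]]) -> PairwiseResult:
    """DerSimonian-Laird random-effects pooling of (effect, se) pairs."""
    studies = list(studies)
    if not studies:
        raise InvalidArgumentError("pairwise_ma needs at least one study")
    y = np.array([e for e, _ in studies], dtype=float)
    se = np.array([s for _, s in studies], dtype=float)
    if (se <= 0).any():
        raise InvalidArgumentError("standard errors must be > 0")
    w = 1.0 / se ** 2
    theta_fixed = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - theta_fixed) ** 2))
    k = len(y)
    if k == 1:
        tau2 = 0.0
    else:
        c = float(np.sum(w) - np.sum(w ** 2) / np.sum(w))
        tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    w_star = 1.0 / (se ** 2 + tau2)
    pooled = float(np.sum(w_star * y) / np.sum(w_star))
    return PairwiseResult(pooled=pooled, se=float(np.sqrt(1.0 / np.sum(w_star))),
                          tau2=tau2, q=q, k=k)


# ---------------------------------------------------------------------------
# Relative-effect container
# ---------------------------------------------------------------------------


@dataclass
class RelativeEffects:
    """NMA output: per-treatment effect versus the reference.

    ``effects[reference] == (0.0, 0.0)`` by construction; ``vcov`` is the
    covariance matrix of the non-reference estimates (order = its index).
    """

    reference: str
    effects: dict[str, tuple[float, float]]  # treatment -> (estimate, se)
    tau2: float
    scale: str  # "mean_difference" | "log_odds_ratio"
    vcov: pd.DataFrame | None = None

    def estimate(self, treatment: str) -> float:
        return self.effects[treatment][0]

    def se(self, treatment: str) -> float:
        return self.effects[treatment][1]

    def odds_ratio(self, treatment: str) -> float:
        if self.scale != "log_odds_ratio":
            raise InvalidArgumentError("odds ratios only defined on the log-OR scale")
        return float(np.exp(self.effects[treatment][0]))

    def contrast(self, a: str, b: str) -> float:
        """Effect of a vs b (difference of basic parameters)."""
        return self.effects[a][0] - self.effects[b][0]

    def league_table(self) -> pd.DataFrame:
        names = sorted(self.effects)
        return pd.DataFrame([[self.contrast(a, b) for b in names] for a in names],
                            index=names, columns=names)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "reference": self.reference, "scale": self.scale, "tau2": self.tau2,
            "effects": {t: {"estimate": e, "se": s} for t, (e, s) in sorted(self.effects.items())},
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# Aggregate-data NMA
# ---------------------------------------------------------------------------


def _check_connected(edges: set[tuple[str, str]], nodes: set[str]) -> None:
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    comps = [sorted(c) for c in nx.connected_components(g)]
    if len(comps) > 1:
        raise NetworkError(
            f"treatment network is disconnected; components: {comps}", components=comps)


def fit_ad_nma(network: pd.DataFrame, reference: str) -> RelativeEffects:
    """Contrast-based random-effects NMA of an aggregate event network.

    ``network`` has columns ``study_id, treatment, n, events``. Studies whose
    arms carry no information (all zero or all full) are dropped; two-by-two
    tables with a zero cell get a 0.5 continuity correction on every cell of
    the study. Reduces exactly to :func:`pairwise_ma` on two-treatment
    networks, and contrasts between non-reference treatments are invariant
    to the choice of reference.
    """
    df = network.copy()
    required = {"study_id", "treatment", "n", "events"}
    if not required <= set(df.columns):
        raise InvalidArgumentError(f"network needs columns {sorted(required)}")
    if ((df["events"] < 0) | (df["events"] > df["n"])).any():
        raise InvalidArgumentError("need 0 <= events <= n in every arm")

    ys, vars_, rows_study, design_rows = [], [], [], []
    treatments = sorted(df["treatment"].unique())
    edges: set[tuple[str, str]] = set()
    kept_nodes: set[str] = set()
    for sid, g in df.groupby("study_id", sort=True):
        g = g.reset_index(drop=True)
        if len(g) < 2:
            continue
        ev = g["events"].to_numpy(dtype=float)
        n = g["n"].to_numpy(dtype=float)
        if (ev == 0).all() or (ev == n).all():
            continue  # zero-information study
        if ((ev == 0) | (ev == n)).any():
            ev = ev + 0.5
            n = n + 1.0
        logodds = np.log(ev / (n - ev))
        var_arm = 1.0 / ev + 1.0 / (n - ev)
        base = 0
        for i in range(1, len(g)):
            ys.append(logodds[i] - logodds[base])
            vars_.append((var_arm[i], var_arm[base]))
            rows_study.append(sid)
            design_rows.append((g.loc[i, "treatment"], g.loc[base, "treatment"]))
            edges.add(tuple(sorted((g.loc[i, "treatment"], g.loc[base, "treatment"]))))
        kept_nodes.update(g["treatment"])
    if not ys:
        raise InvalidArgumentError("no informative studies in the network")
    if reference not in kept_nodes:
        raise InvalidArgumentError(f"reference {reference!r} absent from the network")
    _check_connected(edges, kept_nodes)

    treatments = sorted(kept_nodes)
    baseline = treatments[0]
    params = [t for t in treatments if t != baseline]
    idx = {t: j for j, t in enumerate(params)}
    n_c = len(ys)
    X = np.zeros((n_c, len(params)))
    for r, (t_i, t_b) in enumerate(design_rows):
        if t_i != baseline:
            X[r, idx[t_i]] = 1.0
        if t_b != baseline:
            X[r, idx[t_b]] = -1.0
    y = np.asarray(ys)

    # block-diagonal contrast covariance: shared baseline arm within a study
    V = np.zeros((n_c, n_c))
    R = np.eye(n_c)  # random-effect structure (0.5 within multi-arm studies)
    for i in range(n_c):
        V[i, i] = vars_[i][0] + vars_[i][1]
        for j in range(i + 1, n_c):
            if rows_study[i] == rows_study[j]:
                V[i, j] = V[j, i] = vars_[i][1]  # shared baseline-arm variance
                R[i, j] = R[j, i] = 0.5

    def gls(Vmat):
        W = np.linalg.inv(Vmat)
        XtW = X.T @ W
        cov = np.linalg.inv(XtW @ X)
        beta = cov @ (XtW @ y)
        resid = y - X @ beta
        qstat = float(resid @ W @ resid)
        return beta, cov, W, qstat

    beta0, cov0, W0, q = gls(V)
    dof = n_c - np.linalg.matrix_rank(X)
    if dof > 0:
        P = W0 - W0 @ X @ cov0 @ X.T @ W0
        c = float(np.trace(P @ R))
        tau2 = max(0.0, (q - dof) / c) if c > 0 else 0.0
    else:
        tau2 = 0.0
    beta, cov, _, _ = gls(V + tau2 * R)

    # re-express vs the requested reference
    def basic(t: str) -> np.ndarray:
        v = np.zeros(len(params))
        if t != baseline:
            v[idx[t]] = 1.0
        return v

    effects: dict[str, tuple[float, float]] = {}
    non_ref = [t for t in treatments if t != reference]
    C = np.vstack([basic(t) - basic(reference) for t in non_ref])
    vcov = C @ cov @ C.T
    for t, var in zip(non_ref, np.diag(vcov)):
        est = float(basic(t) @ beta - basic(reference) @ beta)
        effects[t] = (est, float(np.sqrt(max(var, 0.0))))
    effects[reference] = (0.0, 0.0)
    return RelativeEffects(reference=reference, effects=effects, tau2=tau2,
                           scale="log_odds_ratio",
                           vcov=pd.DataFrame(vcov, index=non_ref, columns=non_ref))


# ---------------------------------------------------------------------------
# One-stage IPD-NMA with effect modifiers
# ---------------------------------------------------------------------------


@dataclass
class ModifierModel:
    """Fitted one-stage IPD-NMA: main effects plus covariate interactions.

    ``predict_delta(patient, drug)`` returns the patient-specific mean HDRS
    difference of ``drug`` versus the reference; at the covariate centre it
    equals the treatment main effect, and for the reference drug it is 0.
    """

    reference: str
    treatments: list[str]                       # non-reference arms
    main_effects: dict[str, float]
    interactions: dict[str, float] | dict[tuple[str, str], float]
    centres: dict[str, float]
    tau2: float
    cov_params: pd.DataFrame                    # over trt_/int_ parameter names
    study_intercepts: dict[str, float] = field(default_factory=dict)
    drug_specific: bool = False
    scale: str = "mean_difference"
    converged: bool = True

    def _param_vector(self, patient: Mapping[str, float], drug: str) -> pd.Series:
        c = pd.Series(0.0, index=self.cov_params.index)
        c[f"trt_{drug}"] = 1.0
        for cov, centre in self.centres.items():
            x = float(patient[cov]) - centre
            name = f"int_{drug}__{cov}" if self.drug_specific else f"int_{cov}"
            if name in c.index:
                c[name] += x
        return c

    def predict_delta(self, patient: Mapping[str, float], drug: str) -> tuple[float, float]:
        """(mean difference vs reference, delta-method se) for one patient."""
        if drug == self.reference:
            return 0.0, 0.0
        if drug not in self.treatments:
            raise InvalidArgumentError(f"drug {drug!r} not in the fitted network")
        c = self._param_vector(patient, drug)
        delta = float(c[f"trt_{drug}"] * self.main_effects[drug])
        for cov in self.centres:
            key = (drug, cov) if self.drug_specific else cov
            coef = self.interactions.get(key)
            if coef is not None:
                name = f"int_{drug}__{cov}" if self.drug_specific else f"int_{cov}"
                delta += float(c[name]) * coef
        var = float(c @ self.cov_params.to_numpy() @ c)
        return delta, float(np.sqrt(max(var, 0.0)))

    def to_json(self, path: str | Path | None = None) -> str:
        inter = ({f"{d}::{c}": v for (d, c), v in self.interactions.items()}
                 if self.drug_specific else dict(self.interactions))
        payload = {"reference": self.reference, "treatments": self.treatments,
                   "main_effects": self.main_effects, "interactions": inter,
                   "centres": self.centres, "tau2": self.tau2,
                   "drug_specific": self.drug_specific, "scale": self.scale}
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def fit_ipd_nma(ipd: pd.DataFrame, reference: str,
                modifiers: Sequence[str] = ("hdrs_total", "age"),
                outcome: str = "hdrs_8wk",
                drug_specific: bool = False,
                reml: bool = True) -> ModifierModel:
    """One-stage random-effects IPD network meta-analysis.

    Linear mixed model: fixed study intercepts, fixed treatment effects
    versus ``reference``, fixed covariate main effects, treatment-by-
    covariate interactions (one shared coefficient per covariate across all
    non-reference arms by default, or per (treatment, covariate) with
    ``drug_specific=True``), and a study-by-treatment random effect on
    non-reference arms with a single variance tau^2, estimated by REML.
    """
    import statsmodels.api as sm

    for col in ("study_id", "treatment", outcome, *modifiers):
        if col not in ipd.columns:
            raise InvalidArgumentError(f"IPD lacks required column {col!r}")
    treatments = sorted(ipd["treatment"].unique())
    if reference not in treatments:
        raise InvalidArgumentError(f"reference {reference!r} absent from the IPD")
    edges = {tuple(sorted(p)) for _, g in ipd.groupby("study_id")
             for p in zip(sorted(g["treatment"].unique())[:-1],
                          sorted(g["treatment"].unique())[1:])}
    _check_connected(edges, set(treatments))

    non_ref = [t for t in treatments if t != reference]
    df = ipd.reset_index(drop=True)
    active = (df["treatment"] != reference).to_numpy(dtype=float)
    centres = {m: float(df[m].mean()) for m in modifiers}

    cols: dict[str, np.ndarray] = {}
    studies = sorted(df["study_id"].unique())
    for s in studies:
        cols[f"study_{s}"] = (df["study_id"] == s).to_numpy(dtype=float)
    for t in non_ref:
        cols[f"trt_{t}"] = (df["treatment"] == t).to_numpy(dtype=float)
    for m in modifiers:
        x = df[m].to_numpy(dtype=float) - centres[m]
        cols[f"cov_{m}"] = x
        if drug_specific:
            for t in non_ref:
                cols[f"int_{t}__{m}"] = x * cols[f"trt_{t}"]
        else:
            cols[f"int_{m}"] = x * active

    exog = pd.DataFrame(cols, index=df.index)
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        raise IdentifiabilityError(
            "design is rank deficient (a modifier may be constant within studies)")

    # one variance component spanning the non-reference arm indicators; per
    # study only the arms actually present (all-zero columns are singular)
    vc_colnames, vc_mats = [], []
    for s in studies:
        rows = df["study_id"] == s
        present = [f"trt_{t}" for t in non_ref if exog.loc[rows, f"trt_{t}"].any()]
        vc_colnames.append(present)
        vc_mats.append(exog.loc[rows, present].to_numpy() if present
                       else np.zeros((int(rows.sum()), 0)))
    exog_vc = sm.regression.mixed_linear_model.VCSpec(
        names=["study_treatment"], colnames=[vc_colnames], mats=[vc_mats])
    model = sm.MixedLM(df[outcome].to_numpy(dtype=float), exog,
                       groups=df["study_id"].to_numpy(),
                       exog_re=np.zeros((len(df), 0)),  # no random intercept
                       exog_vc=exog_vc)
    import warnings

    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=reml)

    fe = res.fe_params
    param_names = [n for n in exog.columns if n.startswith(("trt_", "int_"))]
    cov_fe = pd.DataFrame(np.asarray(res.cov_params())[:len(fe), :len(fe)],
                          index=exog.columns, columns=exog.columns)
    cov_sub = cov_fe.loc[param_names, param_names]

    main = {t: float(fe[f"trt_{t}"]) for t in non_ref}
    if drug_specific:
        inter = {(t, m): float(fe[f"int_{t}__{m}"]) for t in non_ref for m in modifiers}
    else:
        inter = {m: float(fe[f"int_{m}"]) for m in modifiers}
    tau2 = float(res.vcomp[0]) if len(res.vcomp) else 0.0
    return ModifierModel(
        reference=reference, treatments=non_ref, main_effects=main,
        interactions=inter, centres=centres, tau2=tau2, cov_params=cov_sub,
        study_intercepts={s: float(fe[f"study_{s}"]) for s in studies},
        drug_specific=drug_specific, converged=bool(res.converged))


def predict_delta(model: ModifierModel, patient: Mapping[str, float],
                  drug: str) -> tuple[float, float]:
    """Functional alias of :meth:`ModifierModel.predict_delta`."""
    return model.predict_delta(patient, drug)
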