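"""Preference-weighted multiple-criteria decision analysis (MCDA).

Predictions for each candidate drug — expected 8-week HDRS, probability of
discontinuation, probabilities of the patient's selected adverse events —
are mapped to a single recommendation value in [0, 1]:

1. top-level weights: efficacy, acceptability and side effects each receive
   0.333 (renormalized to sum to one);
2. the side-effect mass is distributed over the selected adverse events
   (equally, or proportionally to inverse rank when the patient ranked
   them; over *all* modeled events when the patient opted out);
3. each outcome is rescaled by a linear partial value function anchored at
   the worst and best values among the candidate drugs (lower HDRS and
   lower probabilities are better, so the anchors are reversed);
4. the recommendation value is the weighted sum of partial values, drugs
   are ranked by it, and the top three non-excluded drugs are displayed
   with a one-to-five dot strength.

Clinician exclusions are applied *before* the anchors are computed, so an
excluded drug can never distort the scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .combine import PredictionSet
from .errors import (
    DegenerateInputError,
    EmptyCandidateError,
    InvalidArgumentError,
)

__all__ = ["PreferenceInput", "WeightScheme", "Recommendation",
           "allocate_weights", "partial_value", "score_drugs",
           "recommend_top3", "recommend"]

EQUAL_THIRD = 1.0 / 3.0
MAX_SELECTED_AES = 5


class PreferenceInput(BaseModel):
    """Elicited preferences plus clinician exclusions.

    ``selected_aes`` holds at most five modeled adverse events the patient
    most wants to avoid; ``ranks`` (optional) is a permutation of
    ``1..len(selected_aes)`` with 1 = most important. ``elicit_opt_out``
    marks a patient who declined the elicitation (side-effect weight is then
    spread over all modeled events).
    """

    selected_aes: list[str] = Field(default_factory=list, max_length=MAX_SELECTED_AES)
    ranks: list[int] | None = None
    clinician_exclusions: list[str] = Field(default_factory=list)
    elicit_opt_out: bool = False

    @model_validator(mode="after")
    def _check_ranks(self):
        if self.ranks is not None:
            if sorted(self.ranks) != list(range(1, len(self.selected_aes) + 1)):
                raise ValueError("ranks must be a permutation of 1..len(selected_aes)")
        return self


@dataclass
class WeightScheme:
    """Top-level and per-adverse-event weights; sums to one."""

    w_efficacy: float = EQUAL_THIRD
    w_acceptability: float = EQUAL_THIRD
    w_side_effects: float = EQUAL_THIRD
    ae_weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if min(self.w_efficacy, self.w_acceptability, self.w_side_effects) < 0:
            raise InvalidArgumentError("weights must be >= 0")
        total = self.w_efficacy + self.w_acceptability + self.w_side_effects
        if total <= 0:
            raise InvalidArgumentError("at least one weight must be > 0")
        self.w_efficacy /= total
        self.w_acceptability /= total
        self.w_side_effects /= total
        if self.ae_weights:
            s = sum(self.ae_weights.values())
            if s > 0:
                self.ae_weights = {k: v / s * self.w_side_effects
                                   for k, v in self.ae_weights.items()}

    @property
    def total(self) -> float:
        return self.w_efficacy + self.w_acceptability + (
            sum(self.ae_weights.values()) if self.ae_weights else self.w_side_effects)


def allocate_weights(prefs: PreferenceInput, included_aes: Sequence[str],
                     top_level: tuple[float, float, float] = (EQUAL_THIRD,) * 3
                     ) -> WeightScheme:
    """Distribute the side-effect weight over adverse events.

    Equal split over the selected events; proportional to 1/rank when ranks
    were given; over all modeled events when the patient opted out or
    selected none. With no modeled events at all, the side-effect mass is 0
    and the other two criteria are renormalized.
    """
    unknown = set(prefs.selected_aes) - set(included_aes)
    if unknown:
        raise InvalidArgumentError(f"selected adverse events not modeled: {sorted(unknown)}")
    w_eff, w_acc, w_se = top_level
    if prefs.elicit_opt_out or not prefs.selected_aes:
        targets = list(included_aes)
        raw = {ae: 1.0 for ae in targets}
    else:
        targets = list(prefs.selected_aes)
        if prefs.ranks is not None:
            raw = {ae: 1.0 / r for ae, r in zip(targets, prefs.ranks)}
        else:
            raw = {ae: 1.0 for ae in targets}
    if not targets:
        return WeightScheme(w_efficacy=w_eff, w_acceptability=w_acc,
                            w_side_effects=0.0, ae_weights={})
    return WeightScheme(w_efficacy=w_eff, w_acceptability=w_acc,
                        w_side_effects=w_se, ae_weights=raw)


def partial_value(x: float, worst: float, best: float) -> float:
    """Linear partial value: 0 at the worst anchor, 1 at the best, clamped.

    Direction is encoded by anchor order — for outcomes where lower is
    better (HDRS, probabilities) the best anchor is numerically below the
    worst one.
    """
    if worst == best:
        raise DegenerateInputError("degenerate anchors: worst == best")
    return float(np.clip((x - worst) / (best - worst), 0.0, 1.0))


def _outcome_values(pred: PredictionSet, drugs: Sequence[str],
                    weights: WeightScheme) -> dict[str, dict[str, float]]:
    """Per-outcome per-drug raw values for the weighted outcomes."""
    out = {"efficacy": {d: pred.expected_hdrs(d) for d in drugs},
           "acceptability": {d: pred.p_discontinue(d) for d in drugs}}
    for ae in weights.ae_weights:
        out[f"ae_{ae}"] = {d: pred.p_ae(d, ae) for d in drugs}
    return out


def score_drugs(pred: PredictionSet, weights: WeightScheme,
                drugs: Sequence[str] | None = None,
                anchors: str = "local") -> dict[str, float]:
    """Recommendation value in [0, 1] per drug.

    ``anchors="local"`` (default) anchors each outcome's partial value
    function at the per-patient min/max across the candidate drugs —
    maximal discrimination among the actual options. ``anchors="global"``
    uses the clinical scale bounds (HDRS 0-52, probabilities 0-1) instead.
    """
    drugs = list(drugs if drugs is not None else sorted(pred.drugs))
    if not drugs:
        raise EmptyCandidateError("no candidate drugs to score")
    missing_ae = [ae for ae in weights.ae_weights
                  if any(ae not in pred.drugs[d]["p_ae"] for d in drugs)]
    if missing_ae:
        from .errors import ConfigurationError
        raise ConfigurationError(f"predictions missing weighted adverse events: {missing_ae}")
    values = _outcome_values(pred, drugs, weights)
    w = {"efficacy": weights.w_efficacy, "acceptability": weights.w_acceptability}
    if weights.ae_weights:
        w.update({f"ae_{ae}": wk for ae, wk in weights.ae_weights.items()})
    else:
        # no modeled side effects carry weight: spread over the two others
        pass
    scores = {d: 0.0 for d in drugs}
    active_total = sum(w.values())
    for outcome, wk in w.items():
        vals = values[outcome]
        if anchors == "local":
            worst, best = max(vals.values()), min(vals.values())  # lower is better
        elif anchors == "global":
            worst, best = ((52.0, 0.0) if outcome == "efficacy" else (1.0, 0.0))
        else:
            raise InvalidArgumentError(f"unknown anchors mode {anchors!r}")
        for d in drugs:
            if worst == best:
                pv = 0.5  # all candidates tie on this outcome
            else:
                pv = partial_value(vals[d], worst, best)
            scores[d] += (wk / active_total) * pv
    return scores


@dataclass
class Recommendation:
    """Ranked recommendation payload for display."""

    values: dict[str, float]                   # drug -> recommendation value
    ranking: list[str]                         # all candidates, best first
    top3: list[str]
    dot_strength: dict[str, int]               # drug -> 1..5
    ae_breakdown: dict[str, dict[str, float]]  # drug -> selected AE -> prob
    excluded: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {"values": self.values, "ranking": self.ranking,
                   "top3": self.top3, "dot_strength": self.dot_strength,
                   "ae_breakdown": self.ae_breakdown, "excluded": self.excluded}
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _dots(value: float) -> int:
    """Map a [0,1] recommendation value onto 1..5 display dots."""
    return int(1 + np.floor(4.0 * value + 0.5))


def recommend_top3(scores: Mapping[str, float], prefs: PreferenceInput,
                   pred: PredictionSet) -> Recommendation:
    """Assemble the ranked payload from already-computed scores.

    Ties break by better (lower) expected HDRS, then lower discontinuation
    probability, then lexicographic drug name.
    """
    if not scores:
        raise EmptyCandidateError("no scored drugs")

    def sort_key(d: str):
        return (-scores[d], pred.expected_hdrs(d), pred.p_discontinue(d), d)

    ranking = sorted(scores, key=sort_key)
    top3 = ranking[:3]
    breakdown_aes = (prefs.selected_aes if prefs.selected_aes and not prefs.elicit_opt_out
                     else pred.modeled_aes)
    breakdown = {d: {ae: pred.p_ae(d, ae) for ae in breakdown_aes if ae in pred.drugs[d]["p_ae"]}
                 for d in top3}
    return Recommendation(
        values={d: float(scores[d]) for d in ranking},
        ranking=ranking, top3=top3,
        dot_strength={d: _dots(scores[d]) for d in ranking},
        ae_breakdown=breakdown,
        excluded=sorted(set(prefs.clinician_exclusions)))


def recommend(pred: PredictionSet, prefs: PreferenceInput,
              top_level: tuple[float, float, float] = (EQUAL_THIRD,) * 3,
              anchors: str = "local") -> Recommendation:
    """Full MCDA pass: exclusions, weight allocation, scoring, ranking."""
    candidates = [d for d in sorted(pred.drugs) if d not in set(prefs.clinician_exclusions)]
    if not candidates:
        raise EmptyCandidateError("all drugs were excluded by the clinician")
    weights = allocate_weights(prefs, pred.modeled_aes, top_level=top_level)
    sub = PredictionSet(patient_id=pred.patient_id,
                        drugs={d: pred.drugs[d] for d in candidates},
                        provenance=pred.provenance)
    scores = score_drugs(sub, weights, drugs=candidates, anchors=anchors)
    return recommend_top3(scores, prefs, sub)
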