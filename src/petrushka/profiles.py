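"""Validated patient profile.

The profile mirrors the covariate block of the EHR/trial tables:
demographics, depression features (PHQ-9, HDRS total and seven HDRS items),
history flags, comorbidities and co-medications. Validation enforces scale
bounds and simple cross-field consistency (age at first diagnosis cannot
exceed current age); :meth:`PatientProfile.to_row` emits the one-row
covariate table the fitted models consume.
"""

from __future__ import annotations

from typing import Literal

import pandas as pd
from pydantic import BaseModel, Field, model_validator

HDRS_ITEM_BOUNDS = {  # item number -> (low, high)
    3: (0, 4), 4: (0, 2), 6: (0, 2), 10: (0, 4), 11: (0, 4), 13: (0, 2), 17: (0, 2),
}


class PatientProfile(BaseModel):
    """One patient's baseline covariates."""

    age: float = Field(ge=18, le=74)
    sex: Literal["female", "male"]
    ethnicity: str = "white"
    socioeconomic_quintile: int = Field(default=3, ge=1, le=5)
    bmi: float = Field(default=27.0, ge=10, le=80)
    smoking: Literal["never", "ex", "current"] = "never"
    phq9_total: int = Field(ge=0, le=27)
    hdrs_total: int = Field(ge=0, le=52)
    hdrs_items: dict[int, int] = Field(default_factory=dict)

    past_antidepressant: bool = False
    past_ssri: bool = False
    past_fluoxetine: bool = False
    past_psychotherapy: bool = False
    secondary_care_referral: bool = False
    childhood_maltreatment: bool = False
    age_first_diagnosis: float | None = None

    anxiety: bool = False
    chronic_inflammatory_disease: bool = False
    coronary_heart_disease: bool = False
    diabetes: bool = False
    epilepsy_seizures: bool = False
    hypothyroidism: bool = False
    migraine: bool = False
    stroke_tia: bool = False

    anticoagulants: bool = False
    anticonvulsants: bool = False
    antihypertensives: bool = False
    aspirin: bool = False
    bisphosphonates: bool = False
    hypnotics_anxiolytics: bool = False
    hrt: bool = False
    nsaids: bool = False
    oral_contraceptives: bool = False
    statins: bool = False

    @model_validator(mode="after")
    def _consistency(self):
        if self.age_first_diagnosis is not None and self.age_first_diagnosis > self.age:
            raise ValueError("age_first_diagnosis cannot exceed age")
        for item, score in self.hdrs_items.items():
            if item not in HDRS_ITEM_BOUNDS:
                raise ValueError(f"unsupported HDRS item {item}; carried items are "
                                 f"{sorted(HDRS_ITEM_BOUNDS)}")
            lo, hi = HDRS_ITEM_BOUNDS[item]
            if not lo <= score <= hi:
                raise ValueError(f"HDRS item {item} score {score} outside [{lo},{hi}]")
            if score > self.hdrs_total:
                raise ValueError(f"HDRS item {item} exceeds the total score")
        return self

    def to_row(self) -> pd.DataFrame:
        """One-row covariate table on the generator/model column layout."""
        d = self.model_dump()
        items = d.pop("hdrs_items")
        for item, (lo, _) in HDRS_ITEM_BOUNDS.items():
            d[f"hdrs_item_{item}"] = items.get(item, lo)
        if d["age_first_diagnosis"] is None:
            d["age_first_diagnosis"] = d["age"]
        d["sex_female"] = int(d["sex"] == "female")
        for k, v in list(d.items()):
            if isinstance(v, bool):
                d[k] = int(v)
        return pd.DataFrame([d])

    def covariates(self) -> dict[str, float]:
        """Flat numeric mapping (used for patient-specific NMA deltas)."""
        return {k: float(v) for k, v in self.to_row().iloc[0].items()
                if not isinstance(v, str)}
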