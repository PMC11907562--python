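"""Canonical treatment and adverse-event vocabularies.

The engine compares 16 antidepressants (plus placebo, which appears in the
trial network but is never recommended). Fluoxetine is the reference drug for
the efficacy and acceptability analyses because it has the largest
primary-care evidence base; paroxetine is the reference for adverse events
because it has the largest trial arm.
"""

from __future__ import annotations

ANTIDEPRESSANTS: tuple[str, ...] = (
    "agomelatine",
    "amitriptyline",
    "bupropion",
    "citalopram",
    "clomipramine",
    "duloxetine",
    "escitalopram",
    "fluoxetine",
    "fluvoxamine",
    "imipramine",
    "mirtazapine",
    "paroxetine",
    "sertraline",
    "trazodone",
    "venlafaxine",
    "vortioxetine",
)

PLACEBO = "placebo"

#: All 17 nodes of the trial network.
TREATMENTS: tuple[str, ...] = ANTIDEPRESSANTS + (PLACEBO,)

#: Reference drug for efficacy and all-cause discontinuation.
REFERENCE_EFFICACY = "fluoxetine"

#: Reference drug for adverse-event models (largest trial arm).
REFERENCE_AE = "paroxetine"

#: The 30 most common adverse events tracked by the engine.
ADVERSE_EVENTS: tuple[str, ...] = (
    "abnormal_dreams",
    "agitation",
    "anxiety",
    "cold_symptoms",
    "constipation",
    "decreased_appetite",
    "diarrhoea",
    "dizziness",
    "dry_mouth",
    "erectile_disorder",
    "fatigue",
    "headache",
    "hypertension",
    "hypotension",
    "infections",
    "insomnia",
    "nausea",
    "pain",
    "palpitations",
    "respiratory_disorder",
    "sexual_dysfunction",
    "sleepiness",
    "sore_stomach",
    "stomach_pain",
    "sweating",
    "tremor",
    "vision_disorder",
    "vomiting",
    "weight_gain",
    "weight_loss",
)


def validate_treatment(name: str) -> str:
    """Return the canonical (lowercase) treatment name, or raise KeyError."""
    canon = name.strip().lower()
    if canon not in TREATMENTS:
        raise KeyError(f"unknown treatment {name!r}; expected one of {TREATMENTS}")
    return canon


def validate_adverse_event(name: str) -> str:
    """Return the canonical adverse-event name, or raise KeyError."""
    canon = name.strip().lower().replace(" ", "_")
    if canon not in ADVERSE_EVENTS:
        raise KeyError(f"unknown adverse event {name!r}")
    return canon
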