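"""Full pipeline for one patient: predictions, preferences, top-3 ranking.

Runs simulate -> fit -> NMA -> combine -> MCDA for a 47-year-old woman with
moderately severe depression who most wants to avoid anxiety-like side
effects, and whose clinician has ruled out amitriptyline.
"""

import json
from pathlib import Path

from petrushka import PipelineConfig, run_pipeline

config = PipelineConfig(
    seed=11,
    n_ehr=2000, ipd_studies=20, ipd_per_arm=250, ad_per_arm=400,
    patient=dict(age=47, sex="female", phq9_total=18, hdrs_total=26,
                 hdrs_items={3: 1, 4: 2, 6: 1, 10: 3, 11: 2, 13: 2, 17: 0},
                 past_antidepressant=True, anxiety=True),
    prefs=dict(selected_aes=["anxiety", "agitation"],
               ranks=[1, 2],
               clinician_exclusions=["amitriptyline"]),
)
out = run_pipeline(config, Path("scratch") / "example_run")

rec = json.loads((out / "recommendation.json").read_text())
print("ranking (recommendation value in [0,1]):")
for drug in rec["ranking"]:
    print(f"  {drug:<14} {rec['values'][drug]:.3f}  "
          f"{'●' * rec['dot_strength'][drug]}{'○' * (5 - rec['dot_strength'][drug])}")
print(f"\ntop-3: {rec['top3']}  (excluded: {rec['excluded']})")
print("\nfull report:\n")
print((out / "report.txt").read_text())
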