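"""Generate the three synthetic data sources and peek at their shape.

The engine is developed against synthetic stand-ins for its three real data
sources: a primary-care EHR cohort on the reference drug (fluoxetine), trial
IPD over a 17-node antidepressant network, and aggregate arm-level event
tables. All ground-truth parameters are known, so downstream estimates can
be checked against what generated the data.
"""

from petrushka import default_truth, generate_ad_network, generate_ehr_cohort, generate_rct_ipd

truth = default_truth(seed=1)

cohort = generate_ehr_cohort(n=5000, truth=truth, seed=1)
print(f"EHR cohort: {cohort.shape[0]} patients x {cohort.shape[1]} columns")
print(f"  age        {cohort['age'].mean():.1f} +/- {cohort['age'].std():.1f}  "
      "(configured: 44.8 +/- 14.2)")
print(f"  HDRS total {cohort['hdrs_total'].mean():.2f} +/- {cohort['hdrs_total'].std():.2f}  "
      "(configured: 23.85 +/- 3.99)")
print(f"  female     {(cohort['sex'] == 'female').mean():.1%}  (configured: 64.3%)")
print(f"  8-wk PHQ-9 outcome mean {cohort['outcome_phq9_8wk'].mean():.1f}, "
      f"discontinued {cohort['discontinued_8wk'].mean():.1%}")

ipd = generate_rct_ipd(n_studies=20, per_arm_n=200, truth=truth, seed=2)
print(f"\nTrial IPD: {len(ipd)} patients, {ipd['study_id'].nunique()} studies, "
      f"{ipd['treatment'].nunique()} treatments")
arm = ipd.groupby("treatment")["hdrs_8wk"].mean().sort_values()
print("  best three arm means (8-wk HDRS, lower is better):")
print(arm.head(3).round(2).to_string())

net = generate_ad_network(n_studies=20, per_arm_n=400, truth=truth, seed=3)
print(f"\nAggregate dropout network: {len(net)} arms; "
      f"pooled event rate {net['events'].sum() / net['n'].sum():.1%}")
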