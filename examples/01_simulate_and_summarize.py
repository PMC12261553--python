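"""Simulate a claims cohort and summarize it.

Draws a synthetic final-year-of-life claims dataset with the nine default
pathway archetypes, applies the ALS cohort filters (G12.2 present, no
C00-C97 cancer code), and prints the demographic summary split by
palliative-care utilization plus per-service utilization.
"""

from palliseq import (
    demo_config,
    generate_claims,
    select_als_cohort,
    service_utilization,
    summarize_cohort,
)

claims = generate_claims(demo_config(n=600, seed=7))
cohort = select_als_cohort(claims)

print(f"simulated individuals: {len(claims.persons)}")
print(f"cohort after ALS/cancer filters: {len(cohort)}")
print()
print(summarize_cohort(cohort))
print()
with_pc = [m for m in cohort if m.has_palliative_care]
print(service_utilization(with_pc).to_string(index=False))
print()
print("Rows are counts/percentages (half-up, 1 decimal) and median (IQR);")
print("'with_pc' members initiated at least one palliative-care service.")
print("Roughly a fifth of simulated individuals carry a cancer code and are")
print("excluded, mirroring the filter the analysis applies to real claims.")
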