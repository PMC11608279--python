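"""Describe the cohort: high-cost vs non-high-cost patients.

Builds the descriptive table comparing demographics, utilization and
spending across the two strata, including the top chronic conditions
ranked among high-cost patients.
"""

from hicost import (
    SimConfig,
    build_features,
    cohort_table,
    generate_population,
    load_packaged_map,
    select_high_cost,
    summarize_patient_year,
)

patients, encounters, _ = generate_population(SimConfig(n_patients=20_000, seed=42))
summaries = select_high_cost(summarize_patient_year(encounters, patients, 2019))

adrg, elix = load_packaged_map("adrg"), load_packaged_map("elixhauser")
enc19 = encounters[encounters["year"] == 2019]
fm = build_features(summaries, enc19, encounters, patients, adrg, elix)

table = cohort_table(
    summaries, patients,
    chronic_flags=fm.matrix[fm.columns_of("comorbidity")],
    adrg_flags=fm.matrix[fm.columns_of("ADRG")],
)
print(table.to_string(index=False))
# Each cell is mean (SD) or N (%); high-cost patients should be older,
# poorer and far heavier utilizers than the rest.
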