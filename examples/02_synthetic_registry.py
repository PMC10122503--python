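"""Generate a synthetic surgical registry and inspect its confounding.

The generator draws one surgery per patient with status-conditional age,
sex, ASA-class and Charlson-comorbidity distributions, then samples 90-day
complications from a logistic model with modest *conditional* odds ratios
(ex 1.09, current 1.17 vs never).  Because ex-smokers are generated older
and sicker, their *crude* odds ratio is far larger — the classic
confounding pattern this package's adjusted analysis is meant to undo.
"""

from smokesurg.cohort import CohortConfig, generate_cohort
from smokesurg.outcomes import default_definitions, flag_outcomes
from smokesurg.stats import unadjusted_or_table

tables = generate_cohort(CohortConfig(n_patients=20_000, seed=1))
surg = tables.surgeries.merge(
    tables.patients[["patient_id", "sex", "true_status"]], on="patient_id"
)

by = surg.groupby("true_status")
print("median age:", by["age_at_surgery"].median().round(1).to_dict())
print("ASA III-V share:",
      by.apply(lambda g: (g["asa_class"] >= 3).mean(),
               include_groups=False).round(3).to_dict())

overall_def, _ = default_definitions()
flags = flag_outcomes(
    tables.surgeries, tables.diagnosis_events, tables.care_events, overall_def
)
surg = surg.set_index("surgery_id")
surg["overall"] = flags
print("complication rate:",
      surg.groupby("true_status")["overall"].mean().round(3).to_dict())

crude = unadjusted_or_table(
    surg.assign(smoking_status=surg["true_status"]).reset_index(),
    surg["overall"].to_numpy(),
)
print("\ncrude odds ratios vs never:")
print(crude.round(2))
print(
    "\nThe crude ex-smoker OR (~1.6-1.7) greatly exceeds the configured "
    "conditional OR of 1.09: the excess is confounding by age, ASA and "
    "comorbidity, not a causal smoking effect."
)
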