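"""Run the whole synthetic study end to end and print the headline tables.

Simulates a corpus and registry, trains and tunes the classifier,
classifies every patient's status notes, assigns one preoperative status
per surgery, applies the exclusion cascade, scores comorbidity and 90-day
outcomes, and fits the unadjusted and adjusted complication models.
Reports are also written as CSV/JSON under ``scratch/example_run``.
"""

import dataclasses

from smokesurg.cohort import CohortConfig
from smokesurg.corpus import CorpusConfig
from smokesurg.pipeline import RunConfig, run_study

config = dataclasses.replace(
    RunConfig(
        corpus=CorpusConfig(n_sentences=4000),
        cohort=CohortConfig(n_patients=8000),
        min_surgeries_per_specialty=1000,
    ).reseeded(42),
    output_dir="scratch/example_run",
)
report = run_study(config)

print("flow:", report.flow)
print("\nsmoking-status odds ratios (all surgeries):")
all_or = report.or_table[report.or_table["group"] == "all"]
print(all_or.round(2).to_string(index=False))
print("\nvariable importance (overall outcome, all surgeries):")
imp = report.importance.query("group == 'all' and outcome == 'overall'")
print(imp[["variable", "wald_share_pct", "mean_abs_shapley"]]
      .round(2).to_string(index=False))
print(
    "\nAdjustment shrinks the smoking ORs toward their conditional values "
    "(~1.1 ex, ~1.2 current) while ASA class carries most of the "
    "explainable risk, mirroring the structure of real registry analyses."
)
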