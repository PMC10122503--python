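"""Surgery-level status assignment, Charlson scoring and outcome flagging.

Walks three small, fully explicit cases: (1) the most-recent-unless-never
assignment rule on conflicting timestamped notes, (2) Charlson comorbidity
scoring with the metastatic-cancer hierarchy, and (3) the 90-day outcome
window on a toy event history.
"""

from datetime import date
from types import SimpleNamespace

from smokesurg.comorbidity import compute_cci, smoking_related_flags
from smokesurg.outcomes import default_definitions, detect_outcome
from smokesurg.status import StatusObservation, assign_preoperative_status

# 1) a 2019 "never smokes" note cannot erase the 2017 smoking history
obs = [
    StatusObservation("p1", date(2017, 3, 1), "current"),
    StatusObservation("p1", date(2019, 5, 1), "never"),
]
print("assigned status:", assign_preoperative_status(obs, date(2019, 12, 1)))
# -> ex: documented smoking plus a later 'never' means a quit, not a never

# 2) Charlson: metastatic disease supersedes the localized tumour
res = compute_cci({"C50", "C78", "J44", "I21.0"})
print("CCI flags:", sorted(res.present()))
print("count:", res.count, "weighted score:", res.score, "band:", res.category_band)
print("smoking-related:", sorted(smoking_related_flags(res)))

# 3) 90-day window: day 45 pneumonia counts, day 120 code does not
surgery = SimpleNamespace(date=date(2019, 1, 1))
events = [
    SimpleNamespace(icd10_code="J15", date=date(2019, 2, 15)),   # day 45
    SimpleNamespace(icd10_code="J15", date=date(2019, 5, 1)),    # day 120
]
overall, critical = default_definitions()
flag, triggers = detect_outcome(surgery, events, [], overall)
print("overall complication:", flag, "| triggering events:", len(triggers))
flag_crit, _ = detect_outcome(surgery, events, [], critical)
print("critical complication:", flag_crit,
      "(pneumonia is in the overall composite only)")
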