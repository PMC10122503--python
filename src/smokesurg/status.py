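"""Surgery-level preoperative smoking-status assignment.

A patient may carry several classified, timestamped status observations
(current / ex / never; unknowns are filtered upstream).  Each surgery gets
one status by the rule: use only observations dated on or before the
surgery (admission-day notes count as preoperative); take the most recent
one; but if that most recent status is *never* while any earlier
observation says *current* or *ex*, assign *ex* — a never-smoker note
cannot erase documented smoking history.  No preoperative observation at
all yields *unknown*.  Same-day conflicts resolve by the precedence
current > ex > never, conservative toward detecting smoking exposure.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Iterable, Mapping

import pandas as pd

_PRECEDENCE = {"current": 0, "ex": 1, "never": 2}


@dataclass(frozen=True)
class StatusObservation:
    """One classified (patient, date, status) triple; never 'unknown'."""

    patient_id: str
    date: date
    status: str

    def __post_init__(self):
        if self.status not in _PRECEDENCE:
            raise ValueError(f"invalid observation status {self.status!r}")


def assign_preoperative_status(
    observations: Iterable[StatusObservation], surgery_date: date
) -> str:
    """Collapse one patient's observations into a preoperative status.

    Input order never matters; observations dated after surgery never
    contribute.  Returns one of current/ex/never/unknown.
    """
    pre = [o for o in observations if _as_date(o.date) <= _as_date(surgery_date)]
    if not pre:
        return "unknown"
    max_date = max(_as_date(o.date) for o in pre)
    on_max = [o for o in pre if _as_date(o.date) == max_date]
    most_recent = min(on_max, key=lambda o: _PRECEDENCE[o.status])
    if most_recent.status == "never" and any(
        o.status in ("current", "ex") for o in pre
    ):
        return "ex"
    return most_recent.status


def _as_date(value) -> date:
    if isinstance(value, date):
        return value
    return pd.Timestamp(value).date()


def assign_statuses(
    status_observations: pd.DataFrame, surgeries: pd.DataFrame
) -> pd.Series:
    """Per-surgery status from an observation table (patient_id, date, status)."""
    obs_by_patient: dict = {}
    for row in status_observations.itertuples(index=False):
        obs_by_patient.setdefault(row.patient_id, []).append(
            StatusObservation(row.patient_id, _as_date(row.date), row.status)
        )
    out = {}
    for row in surgeries.itertuples(index=False):
        obs = obs_by_patient.get(row.patient_id, [])
        out[row.surgery_id] = assign_preoperative_status(obs, _as_date(row.date))
    return pd.Series(out, name="smoking_status").rename_axis("surgery_id")


def build_analysis_set(
    surgeries: pd.DataFrame, statuses: Mapping | pd.Series
) -> tuple[pd.DataFrame, dict]:
    """Apply the exclusion cascade and emit a flow-diagram count table.

    Exclusion reasons, applied in order (each surgery counted once at its
    first failing check): unknown smoking status, age below 16, missing ASA
    class.  Returns the retained surgeries (with a ``smoking_status``
    column) and a dict of flow counts that reconcile exactly:
    ``final + sum(excluded) == input``.
    """
    frame = surgeries.copy()
    frame["smoking_status"] = frame["surgery_id"].map(statuses)

    unknown = frame["smoking_status"].isna() | (frame["smoking_status"] == "unknown")
    underage = ~unknown & (frame["age_at_surgery"] < 16)
    missing_asa = ~unknown & ~underage & frame["asa_class"].isna()
    keep = ~(unknown | underage | missing_asa)

    flow = {
        "input": int(len(frame)),
        "excluded_unknown_status": int(unknown.sum()),
        "excluded_age_below_16": int(underage.sum()),
        "excluded_missing_asa": int(missing_asa.sum()),
        "final": int(keep.sum()),
    }
    return frame[keep].reset_index(drop=True), flow
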