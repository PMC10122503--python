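"""90-day postoperative complication outcomes.

An outcome is a composite definition: a set of ICD-10 prefixes plus a set of
registry care-event kinds (death, reoperation, readmission, ICU admission or
mechanical ventilation).  A surgery is flagged when any matching diagnosis
or care event falls within the follow-up window, which runs from the day of
surgery (perioperative events count) through day ``window_days`` inclusive.

Two composites are provided by default: the *overall* 90-day complication
(representative ICD-10 prefixes for wound, cardiovascular, neurological,
respiratory, thromboembolic, gastroenterological, urinary and orthopaedic
complications and unspecified bacterial infections, plus all four care-event
kinds) and the *critical* subset (life-threatening complications and death:
acute coronary syndrome, shock, cerebral infarction, pulmonary embolism,
peritonitis, ICU admission or ventilation, and death).  Re-interventions and
readmissions are deliberately excluded from the critical composite.  The
shipped ICD-10 prefix lists are representative, not exhaustive, and fully
overridable via CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable

import pandas as pd

from .comorbidity import normalize_icd10

CARE_EVENT_KINDS = ("death", "reoperation", "readmission", "icu_or_ventilation")

_CRITICAL_PREFIXES = (
    "I21",  # acute myocardial infarction (acute coronary syndrome)
    "I22",
    "I24",
    "R57",  # shock
    "I63",  # cerebral infarction
    "I26",  # pulmonary embolism
    "K65",  # peritonitis
)

_OVERALL_ONLY_PREFIXES = (
    "T79",  # early trauma/surgery complications
    "T81",  # complications of procedures (wound)
    "T84",  # complications of internal orthopaedic devices
    "M96",  # postprocedural musculoskeletal disorders
    "I46",  # cardiac arrest
    "I47",  # paroxysmal tachycardia
    "I50",  # heart failure
    "I60",  # intracranial haemorrhages / stroke
    "I61",
    "I64",
    "G45",  # TIA
    "J12",  # pneumonias
    "J13",
    "J14",
    "J15",
    "J16",
    "J17",
    "J18",
    "J80",  # ARDS
    "J81",  # pulmonary oedema
    "J95",  # postprocedural respiratory disorders
    "J96",  # respiratory failure
    "I80",  # thrombophlebitis / venous thrombosis
    "I82",
    "K56",  # ileus
    "K91",  # postprocedural digestive disorders
    "N10",  # acute pyelonephritis
    "N17",  # acute renal failure
    "N39",  # urinary tract infection
    "A40",  # sepsis / unspecified bacterial infections
    "A41",
    "A49",
)


@dataclass(frozen=True)
class OutcomeDefinition:
    """Composite outcome: ICD-10 prefixes + care-event kinds + window."""

    name: str
    icd10_prefixes: frozenset[str]
    care_event_kinds: frozenset[str]
    window_days: int = 90

    def __post_init__(self):
        if self.window_days < 0:
            raise ValueError("window_days must be >= 0")
        if not self.icd10_prefixes and not self.care_event_kinds:
            raise ValueError("definition needs at least one prefix or event kind")
        unknown = self.care_event_kinds - set(CARE_EVENT_KINDS)
        if unknown:
            raise ValueError(f"unknown care-event kinds: {sorted(unknown)}")


@dataclass(frozen=True)
class OutcomeFlag:
    surgery_id: object
    overall: bool
    critical: bool
    triggering_events: tuple = field(default=())


def default_definitions() -> tuple[OutcomeDefinition, OutcomeDefinition]:
    """(overall, critical) default composites; critical is a strict subset."""
    critical = OutcomeDefinition(
        name="critical_90d",
        icd10_prefixes=frozenset(_CRITICAL_PREFIXES),
        care_event_kinds=frozenset({"icu_or_ventilation", "death"}),
    )
    overall = OutcomeDefinition(
        name="overall_90d",
        icd10_prefixes=frozenset(_CRITICAL_PREFIXES + _OVERALL_ONLY_PREFIXES),
        care_event_kinds=frozenset(CARE_EVENT_KINDS),
    )
    return overall, critical


def read_definition_csv(path) -> OutcomeDefinition:
    """Load a definition from a (name, type, value) CSV; type in {icd, event}."""
    frame = pd.read_csv(path)
    name = str(frame["name"].iloc[0])
    icd = frozenset(
        normalize_icd10(v) for v in frame.loc[frame["type"] == "icd", "value"]
    )
    events = frozenset(str(v) for v in frame.loc[frame["type"] == "event", "value"])
    window = (
        int(frame["window_days"].iloc[0]) if "window_days" in frame.columns else 90
    )
    return OutcomeDefinition(
        name=name, icd10_prefixes=icd, care_event_kinds=events, window_days=window
    )


def write_definition_csv(definition: OutcomeDefinition, path) -> None:
    rows = [
        {"name": definition.name, "type": "icd", "value": p,
         "window_days": definition.window_days}
        for p in sorted(definition.icd10_prefixes)
    ] + [
        {"name": definition.name, "type": "event", "value": k,
         "window_days": definition.window_days}
        for k in sorted(definition.care_event_kinds)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _in_window(event_date: date, surgery_date: date, window_days: int) -> bool:
    return surgery_date <= event_date <= surgery_date + timedelta(days=window_days)


def detect_outcome(
    surgery,
    diagnosis_events: Iterable,
    care_events: Iterable,
    definition: OutcomeDefinition,
) -> tuple[bool, list]:
    """Flag one surgery; returns (flag, triggering events) for audit.

    ``surgery`` needs ``date`` (and events ``date`` plus ``icd10_code`` or
    ``kind``); events predating surgery or outside the window are ignored.
    """
    surgery_date = _as_date(surgery.date if hasattr(surgery, "date") else surgery)
    triggers = []
    for ev in diagnosis_events:
        if not _in_window(_as_date(ev.date), surgery_date, definition.window_days):
            continue
        code = normalize_icd10(str(ev.icd10_code))
        if any(code.startswith(p) for p in definition.icd10_prefixes):
            triggers.append(ev)
    for ev in care_events:
        if not _in_window(_as_date(ev.date), surgery_date, definition.window_days):
            continue
        if ev.kind in definition.care_event_kinds:
            triggers.append(ev)
    return bool(triggers), triggers


def _as_date(value) -> date:
    if isinstance(value, date):
        return value
    return pd.Timestamp(value).date()


def flag_outcomes(
    surgeries: pd.DataFrame,
    diagnosis_events: pd.DataFrame,
    care_events: pd.DataFrame,
    definition: OutcomeDefinition,
) -> pd.Series:
    """Vectorized per-surgery flags; boolean Series indexed by surgery_id.

    Equivalent to :func:`detect_outcome` applied row-wise (asserted in the
    test suite) but joins events to surgeries in bulk.
    """
    surg = surgeries[["surgery_id", "patient_id", "date"]].copy()
    surg["date"] = pd.to_datetime(surg["date"])
    flags = pd.Series(False, index=surg["surgery_id"], name=definition.name)

    window = pd.Timedelta(days=definition.window_days)
    if len(diagnosis_events) and definition.icd10_prefixes:
        ev = diagnosis_events.copy()
        ev["date"] = pd.to_datetime(ev["date"])
        codes = ev["icd10_code"].astype(str).str.upper().str.replace(".", "", regex=False)
        pattern = "|".join(sorted(definition.icd10_prefixes))
        ev = ev[codes.str.match(f"(?:{pattern})")]
        m = surg.merge(ev, on="patient_id", suffixes=("_surg", "_ev"))
        hit = m[(m["date_ev"] >= m["date_surg"]) & (m["date_ev"] <= m["date_surg"] + window)]
        flags.loc[hit["surgery_id"].unique()] = True
    if len(care_events) and definition.care_event_kinds:
        ev = care_events.copy()
        ev["date"] = pd.to_datetime(ev["date"])
        ev = ev[ev["kind"].isin(definition.care_event_kinds)]
        m = surg.merge(ev, on="patient_id", suffixes=("_surg", "_ev"))
        hit = m[(m["date_ev"] >= m["date_surg"]) & (m["date_ev"] <= m["date_surg"] + window)]
        flags.loc[hit["surgery_id"].unique()] = True
    return flags
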