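"""Synthetic surgical registry with realistic confounding structure.

Generates a cohort of patients (one surgery each by default) whose
age/sex/ASA/comorbidity distributions are conditioned on true smoking
status the way a real surgical registry is: ex-smokers are the oldest and
carry the heaviest ASA and comorbidity load, so their *unadjusted* odds
ratio of complications is inflated well above the *conditional* (adjusted)
odds ratio the outcome model is generated with.  Complications are drawn
from a logistic model on (status, age, sex, ASA class, Charlson count
band) with configurable conditional odds ratios; the critical composite is
generated as a subset of the overall composite.  Complication events are
materialized as ICD-10 diagnosis events in days 0–90 after surgery or as
care events (death, reoperation, readmission, ICU/ventilation); noise
diagnoses are placed outside the window to exercise downstream filtering.

Timestamped smoking-status notes are emitted per patient; a configurable
fraction of ex-/current-smokers carry conflicting note sequences that the
most-recent-unless-never assignment rule still resolves to the true
status.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .comorbidity import CharlsonMap, count_band, load_default_map

STATUS_ORDER: tuple[str, ...] = ("never", "ex", "current")

# Representative ICD-10 code emitted per Charlson category.  The
# cerebrovascular code is a sequela code so pre-operative comorbidity never
# collides with the acute-stroke outcome prefix.
_CATEGORY_CODES: Mapping[str, str] = {
    "myocardial_infarction": "I21",
    "congestive_heart_failure": "I50",
    "peripheral_vascular_disease": "I70",
    "cerebrovascular_disease": "I69",
    "chronic_pulmonary_disease": "J44",
    "hemiplegia_paraplegia": "G81",
    "cancer": "C50",
    "metastatic_solid_tumour": "C78",
    "diabetes_without_complication": "E119",
}

_OVERALL_ONLY_EVENT_CODES = (
    "T81", "J15", "N39", "I80", "K91", "A41", "M96", "K56", "N17", "T84",
)
_CRITICAL_EVENT_CODES = ("I21", "I63", "I26", "K65", "R57")
# benign codes outside every outcome and Charlson prefix list
_NOISE_CODES = ("Z00", "H52", "M54", "J06", "L20")

_DEFAULT_SPECIALTY_MIX = {
    "gastroenterological": 0.170,
    "orthopaedic": 0.154,
    "gynaecological": 0.118,
    "plastic": 0.077,
    "otorhinolaryngological": 0.069,
    "vascular": 0.058,
    "breast": 0.049,
    "other": 0.305,
}


def _default_age_params():
    return {"never": (56.0, 18.0), "ex": (64.0, 14.0), "current": (53.0, 16.0)}


def _default_male_fraction():
    return {"never": 0.357, "ex": 0.588, "current": 0.514}


def _default_asa_probs():
    return {
        "never": (0.218, 0.420, 0.279, 0.077, 0.006),
        "ex": (0.067, 0.299, 0.429, 0.193, 0.012),
        "current": (0.110, 0.405, 0.344, 0.129, 0.012),
    }


def _default_comorbidity_probs():
    # category -> prevalence per status (never, ex, current)
    return {
        "myocardial_infarction": (0.023, 0.063, 0.035),
        "congestive_heart_failure": (0.027, 0.077, 0.030),
        "peripheral_vascular_disease": (0.044, 0.150, 0.107),
        "cerebrovascular_disease": (0.063, 0.117, 0.079),
        "chronic_pulmonary_disease": (0.054, 0.162, 0.097),
        "hemiplegia_paraplegia": (0.003, 0.004, 0.004),
        "cancer": (0.205, 0.298, 0.168),
        "metastatic_solid_tumour": (0.014, 0.025, 0.015),
        "diabetes_without_complication": (0.056, 0.104, 0.079),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Cohort generator settings; defaults mirror the study's marginals.

    ``status_mix`` is ordered (never, ex, current); the conditional odds
    ratios are (ex, current) versus never on the respective outcome.
    """

    n_patients: int = 20_000
    status_mix: tuple[float, float, float] = (0.5687, 0.1456, 0.2857)
    conditional_or_overall: tuple[float, float] = (1.09, 1.17)
    conditional_or_critical: tuple[float, float] = (1.09, 1.21)
    baseline_risk: float = 0.31
    baseline_risk_critical: float = 0.033
    age_params: Mapping[str, tuple[float, float]] = field(
        default_factory=_default_age_params
    )
    male_fraction: Mapping[str, float] = field(default_factory=_default_male_fraction)
    asa_probs: Mapping[str, tuple[float, ...]] = field(
        default_factory=_default_asa_probs
    )
    comorbidity_probs: Mapping[str, tuple[float, float, float]] = field(
        default_factory=_default_comorbidity_probs
    )
    specialty_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SPECIALTY_MIX)
    )
    conflict_note_rate: float = 0.05
    note_missing_rate: float = 0.03
    comorbidity_frailty_sd: float = 1.0
    # non-status covariate effects of the outcome models, log-odds scale
    age_coef_overall: float = 0.010
    age_coef_critical: float = 0.015
    male_coef: float = 0.10
    asa_coefs_overall: tuple[float, ...] = (0.0, 0.35, 0.80, 1.30, 1.80)
    asa_coefs_critical: tuple[float, ...] = (0.0, 0.60, 1.50, 2.50, 3.50)
    cci_coefs_overall: tuple[float, ...] = (0.0, 0.25, 0.45, 0.65, 0.85, 1.10)
    cci_coefs_critical: tuple[float, ...] = (0.0, 0.30, 0.55, 0.80, 1.00, 1.30)
    seed: int = 0

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for name, vec in (
            ("status_mix", self.status_mix),
            ("specialty_mix", tuple(self.specialty_mix.values())),
        ):
            arr = np.asarray(vec, dtype=float)
            if (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be non-negative and sum to 1")
        for status, probs in self.asa_probs.items():
            arr = np.asarray(probs, dtype=float)
            if abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError(f"asa_probs[{status}] must sum to 1")
        for ors in (self.conditional_or_overall, self.conditional_or_critical):
            if any(v <= 0 for v in ors):
                raise ValueError("odds ratios must be positive")
        for risk in (self.baseline_risk, self.baseline_risk_critical):
            if not 0.0 < risk < 1.0:
                raise ValueError("baseline risks must lie in (0, 1)")
        if not 0.0 <= self.conflict_note_rate <= 1.0:
            raise ValueError("conflict_note_rate must lie in [0, 1]")


@dataclass(frozen=True)
class CohortTables:
    """The five registry tables produced by :func:`generate_cohort`."""

    patients: pd.DataFrame
    surgeries: pd.DataFrame
    diagnosis_events: pd.DataFrame
    care_events: pd.DataFrame
    status_notes: pd.DataFrame


def _supersede_flags(flags: pd.DataFrame, cmap: CharlsonMap) -> pd.DataFrame:
    out = flags.copy()
    for winner, loser in cmap.supersedes.items():
        if winner in out.columns and loser in out.columns:
            out.loc[out[winner], loser] = False
    return out


def _calibrate_intercept(eta_rest_ref: np.ndarray, target: float) -> float:
    """Intercept such that mean(sigmoid(b0 + eta)) over the reference group
    hits the target marginal risk."""
    return brentq(
        lambda b0: expit(b0 + eta_rest_ref).mean() - target, -30.0, 10.0, xtol=1e-10
    )


def generate_cohort(config: CohortConfig | None = None) -> CohortTables:
    """Generate the synthetic registry; deterministic given ``config.seed``."""
    cfg = config or CohortConfig()
    if cfg.n_patients < 100:
        warnings.warn(
            "n_patients < 100: empirical marginals will be unstable", stacklevel=2
        )
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    cmap = load_default_map()

    status_idx = rng.choice(3, size=n, p=np.asarray(cfg.status_mix))
    status = np.array(STATUS_ORDER, dtype=object)[status_idx]

    loc = np.array([cfg.age_params[s][0] for s in STATUS_ORDER])[status_idx]
    scale = np.array([cfg.age_params[s][1] for s in STATUS_ORDER])[status_idx]
    age = truncnorm.rvs(
        (16.0 - loc) / scale, (100.0 - loc) / scale, loc=loc, scale=scale,
        size=n, random_state=rng,
    )

    male = rng.random(n) < np.array(
        [cfg.male_fraction[s] for s in STATUS_ORDER]
    )[status_idx]

    asa = np.empty(n, dtype=np.int64)
    for si, s in enumerate(STATUS_ORDER):
        mask = status_idx == si
        asa[mask] = rng.choice(
            np.arange(1, 6), size=int(mask.sum()), p=np.asarray(cfg.asa_probs[s])
        )

    categories = list(cfg.comorbidity_probs)
    prev = np.array([cfg.comorbidity_probs[c] for c in categories])  # (k, 3)
    # patient-level frailty correlates comorbidities (multimorbidity tail);
    # lognormal with mean 1 keeps marginal prevalences approximately intact
    frailty = rng.lognormal(
        mean=-cfg.comorbidity_frailty_sd**2 / 2,
        sigma=cfg.comorbidity_frailty_sd,
        size=n,
    )
    p_pat = 1.0 - (1.0 - prev[:, status_idx].T) ** frailty[:, None]
    flags = pd.DataFrame(rng.random((n, len(categories))) < p_pat, columns=categories)
    flags_resolved = _supersede_flags(flags, cmap)
    cci_count = flags_resolved.sum(axis=1).to_numpy()
    cci_band = np.array([count_band(int(c)) for c in cci_count], dtype=object)

    surgery_date = np.datetime64("2015-01-01") + rng.integers(
        0, 1826, size=n
    ).astype("timedelta64[D]")
    birth_date = surgery_date - (age * 365.25).astype("timedelta64[D]")

    specialties = np.array(list(cfg.specialty_mix), dtype=object)
    specialty = specialties[
        rng.choice(len(specialties), size=n, p=np.asarray(list(cfg.specialty_mix.values())))
    ]

    patient_id = np.array([f"P{i:06d}" for i in range(n)], dtype=object)
    surgery_id = np.array([f"S{i:06d}" for i in range(n)], dtype=object)

    # outcome models on the log-odds scale
    band_idx = np.minimum(cci_count, 5)
    status_log_or_overall = np.array(
        [0.0, np.log(cfg.conditional_or_overall[0]), np.log(cfg.conditional_or_overall[1])]
    )
    status_log_or_critical = np.array(
        [0.0, np.log(cfg.conditional_or_critical[0]), np.log(cfg.conditional_or_critical[1])]
    )
    eta_rest_ov = (
        cfg.age_coef_overall * age
        + cfg.male_coef * male
        + np.asarray(cfg.asa_coefs_overall)[asa - 1]
        + np.asarray(cfg.cci_coefs_overall)[band_idx]
    )
    eta_rest_cr = (
        cfg.age_coef_critical * age
        + cfg.male_coef * male
        + np.asarray(cfg.asa_coefs_critical)[asa - 1]
        + np.asarray(cfg.cci_coefs_critical)[band_idx]
    )
    never = status_idx == 0
    b0_ov = _calibrate_intercept(eta_rest_ov[never], cfg.baseline_risk)
    b0_cr = _calibrate_intercept(eta_rest_cr[never], cfg.baseline_risk_critical)
    p_ov = expit(b0_ov + status_log_or_overall[status_idx] + eta_rest_ov)
    p_cr = expit(b0_cr + status_log_or_critical[status_idx] + eta_rest_cr)

    critical = rng.random(n) < p_cr
    p_extra = np.clip((p_ov - p_cr) / (1.0 - p_cr), 0.0, 1.0)
    overall = critical | (rng.random(n) < p_extra)

    patients = pd.DataFrame(
        {
            "patient_id": patient_id,
            "sex": np.where(male, "male", "female"),
            "birth_date": pd.to_datetime(birth_date),
            "true_status": status,
        }
    )
    surgeries = pd.DataFrame(
        {
            "surgery_id": surgery_id,
            "patient_id": patient_id,
            "date": pd.to_datetime(surgery_date),
            "specialty": specialty,
            "asa_class": asa,
            "age_at_surgery": np.round(age, 1),
            "cci_count": cci_count,
            "cci_band": cci_band,
        }
    )

    # --- diagnosis events: pre-operative comorbidity codes -----------------
    dx_frames = []
    flag_mat = flags_resolved.to_numpy()
    pat_ix, cat_ix = np.nonzero(flag_mat)
    if len(pat_ix):
        days_before = rng.integers(30, 3651, size=len(pat_ix))
        dx_frames.append(
            pd.DataFrame(
                {
                    "patient_id": patient_id[pat_ix],
                    "icd10_code": np.array(
                        [_CATEGORY_CODES[categories[j]] for j in cat_ix], dtype=object
                    ),
                    "date": pd.to_datetime(
                        surgery_date[pat_ix] - days_before.astype("timedelta64[D]")
                    ),
                }
            )
        )

    # --- complication triggers ---------------------------------------------
    crit_ix = np.flatnonzero(critical)
    death = np.zeros(n, dtype=bool)
    care_frames = []
    if len(crit_ix):
        u = rng.random(len(crit_ix))
        day = rng.integers(0, 91, size=len(crit_ix))
        codes = np.array(_CRITICAL_EVENT_CODES, dtype=object)[
            rng.integers(0, len(_CRITICAL_EVENT_CODES), size=len(crit_ix))
        ]
        when = pd.to_datetime(surgery_date[crit_ix]) + pd.to_timedelta(day, unit="D")
        dx_mask = u < 0.5
        icu_mask = (u >= 0.5) & (u < 0.8)
        death_mask = u >= 0.8
        death[crit_ix[death_mask]] = True
        dx_frames.append(
            pd.DataFrame(
                {
                    "patient_id": patient_id[crit_ix][dx_mask],
                    "icd10_code": codes[dx_mask],
                    "date": when[dx_mask],
                }
            )
        )
        care_frames.append(
            pd.DataFrame(
                {
                    "patient_id": patient_id[crit_ix][icu_mask | death_mask],
                    "kind": np.where(
                        icu_mask[icu_mask | death_mask], "icu_or_ventilation", "death"
                    ),
                    "date": when[icu_mask | death_mask],
                }
            )
        )

    extra_ix = np.flatnonzero(overall & ~critical)
    if len(extra_ix):
        u = rng.random(len(extra_ix))
        day = rng.integers(0, 91, size=len(extra_ix))
        code_pick = rng.integers(0, len(_OVERALL_ONLY_EVENT_CODES), size=len(extra_ix))
        kind_pick = rng.integers(0, 2, size=len(extra_ix))
        dx_mask = u < 0.6
        when = pd.to_datetime(surgery_date[extra_ix]) + pd.to_timedelta(day, unit="D")
        dx_frames.append(
            pd.DataFrame(
                {
                    "patient_id": patient_id[extra_ix][dx_mask],
                    "icd10_code": np.array(_OVERALL_ONLY_EVENT_CODES, dtype=object)[
                        code_pick[dx_mask]
                    ],
                    "date": when[dx_mask],
                }
            )
        )
        kinds = np.array(["reoperation", "readmission"], dtype=object)[kind_pick]
        care_frames.append(
            pd.DataFrame(
                {
                    "patient_id": patient_id[extra_ix][~dx_mask],
                    "kind": kinds[~dx_mask],
                    "date": when[~dx_mask],
                }
            )
        )

    # --- noise diagnoses outside the 90-day window --------------------------
    noise_mask = (rng.random(n) < 0.10) & ~death
    noise_ix = np.flatnonzero(noise_mask)
    if len(noise_ix):
        day = rng.integers(91, 366, size=len(noise_ix))
        dx_frames.append(
            pd.DataFrame(
                {
                    "patient_id": patient_id[noise_ix],
                    "icd10_code": np.array(_NOISE_CODES, dtype=object)[
                        rng.integers(0, len(_NOISE_CODES), size=len(noise_ix))
                    ],
                    "date": pd.to_datetime(surgery_date[noise_ix])
                    + pd.to_timedelta(day, unit="D"),
                }
            )
        )

    diagnosis_events = (
        pd.concat(dx_frames, ignore_index=True)
        if dx_frames
        else pd.DataFrame(columns=["patient_id", "icd10_code", "date"])
    )
    care_events = (
        pd.concat(care_frames, ignore_index=True)
        if care_frames
        else pd.DataFrame(columns=["patient_id", "kind", "date"])
    )

    status_notes = _generate_status_notes(cfg, rng, patient_id, status_idx, surgery_date)

    return CohortTables(
        patients=patients,
        surgeries=surgeries,
        diagnosis_events=diagnosis_events.sort_values(
            ["patient_id", "date"], kind="stable"
        ).reset_index(drop=True),
        care_events=care_events,
        status_notes=status_notes,
    )


def _generate_status_notes(cfg, rng, patient_id, status_idx, surgery_date):
    """Timestamped per-patient status notes, some deliberately conflicting.

    Conflicts are only injected for ex-/current-smokers, in patterns the
    most-recent-unless-never rule resolves back to the true status; the
    injection probability is scaled so the cohort-wide conflict fraction
    approximates ``conflict_note_rate``.
    """
    n = len(patient_id)
    has_notes = rng.random(n) >= cfg.note_missing_rate
    excurrent = status_idx > 0
    p_mass = cfg.status_mix[1] + cfg.status_mix[2]
    p_conf = min(1.0, cfg.conflict_note_rate / p_mass) if p_mass else 0.0
    conflict = has_notes & excurrent & (rng.random(n) < p_conf)
    two_notes = conflict | (has_notes & (rng.random(n) < 0.4))

    d_recent = rng.integers(1, 731, size=n)
    d_older = d_recent + rng.integers(1, 731, size=n)

    truth = np.array(STATUS_ORDER, dtype=object)[status_idx]
    # conflicting pair resolving to the truth under the assignment rule
    older_conf = np.where(
        status_idx == 1,  # ex: older note says current
        "current",
        np.where(rng.random(n) < 0.5, "ex", "never"),  # current: older ex/never
    ).astype(object)
    recent_conf = np.where(
        status_idx == 1,
        np.where(rng.random(n) < 0.5, "never", "ex"),  # ex: recent never or ex
        "current",
    ).astype(object)

    recent_status = np.where(conflict, recent_conf, truth)
    older_status = np.where(conflict, older_conf, truth)

    frames = [
        pd.DataFrame(
            {
                "patient_id": patient_id[has_notes],
                "date": pd.to_datetime(surgery_date[has_notes])
                - pd.to_timedelta(d_recent[has_notes], unit="D"),
                "status": recent_status[has_notes],
                "conflict": conflict[has_notes],
            }
        ),
        pd.DataFrame(
            {
                "patient_id": patient_id[two_notes],
                "date": pd.to_datetime(surgery_date[two_notes])
                - pd.to_timedelta(d_older[two_notes], unit="D"),
                "status": older_status[two_notes],
                "conflict": conflict[two_notes],
            }
        ),
    ]
    return (
        pd.concat(frames, ignore_index=True)
        .sort_values(["patient_id", "date"], kind="stable")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# registry I/O (four CSV tables + status notes, ISO-8601 dates)

_TABLE_NAMES = (
    "patients", "surgeries", "diagnosis_events", "care_events", "status_notes"
)


def write_registry(tables: CohortTables, directory) -> None:
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in _TABLE_NAMES:
        frame = getattr(tables, name).copy()
        for col in frame.columns:
            if pd.api.types.is_datetime64_any_dtype(frame[col]):
                frame[col] = frame[col].dt.strftime("%Y-%m-%d")
        frame.to_csv(directory / f"{name}.csv", index=False)


def read_registry(directory) -> CohortTables:
    from pathlib import Path

    directory = Path(directory)
    loaded = {}
    for name in _TABLE_NAMES:
        frame = pd.read_csv(directory / f"{name}.csv")
        for col in ("date", "birth_date"):
            if col in frame.columns:
                frame[col] = pd.to_datetime(frame[col])
        loaded[name] = frame
    return CohortTables(**loaded)
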