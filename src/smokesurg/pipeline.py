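"""End-to-end study pipeline: simulate → classify → assign → score → analyze.

Runs the whole chain on a synthetic registry with one seed: generate the
sentence corpus and cohort, train and threshold-tune the smoking-status
classifier, render and classify each patient's status notes, assign one
preoperative status per surgery, apply the exclusion cascade, compute the
Charlson index and the 90-day outcome flags, and estimate unadjusted and
adjusted odds ratios plus variable-importance tables — for all surgeries
and per specialty where the surgery count clears a configurable threshold
(default 10 000).  Every stage logs its input/output row counts and
persists its output as CSV/JSON so each module remains independently
inspectable; a rerun with the same seed reproduces the reports
byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import corpus as corpus_mod
from . import nlp
from .cohort import CohortConfig, CohortTables, generate_cohort, write_registry
from .comorbidity import cci_table
from .corpus import CorpusConfig, generate_corpus, render_sentence
from .outcomes import default_definitions, flag_outcomes
from .stats import (
    collapse_sparse_levels,
    default_model_spec,
    fit_logistic,
    importance_report,
    unadjusted_or_table,
)
from .status import assign_statuses, build_analysis_set

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """One-config description of a full study run."""

    corpus: CorpusConfig = field(default_factory=CorpusConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    nlp_train: nlp.TrainConfig = field(default_factory=nlp.TrainConfig)
    min_precision_known: float = 0.95
    grid_step: float = 0.05
    min_surgeries_per_specialty: int = 10_000
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        seed = int(raw.get("seed", 0))
        cfg = cls(
            corpus=CorpusConfig(**raw.get("corpus", {})),
            cohort=CohortConfig(**raw.get("cohort", {})),
            nlp_train=nlp.TrainConfig(**raw.get("nlp_train", {})),
            min_precision_known=float(raw.get("min_precision_known", 0.95)),
            grid_step=float(raw.get("grid_step", 0.05)),
            min_surgeries_per_specialty=int(
                raw.get("min_surgeries_per_specialty", 10_000)
            ),
            seed=seed,
            output_dir=raw.get("output_dir"),
        )
        return cfg.reseeded(seed)

    def reseeded(self, seed: int) -> "RunConfig":
        """Propagate one master seed into every stochastic component."""
        ss = np.random.SeedSequence(seed)
        s_corpus, s_cohort, s_nlp = (
            int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
        )
        return replace(
            self,
            seed=seed,
            corpus=replace(self.corpus, seed=s_corpus),
            cohort=replace(self.cohort, seed=s_cohort),
            nlp_train=replace(self.nlp_train, seed=s_nlp),
        )


@dataclass
class StudyReport:
    """All pipeline outputs: flow counts, tables and the NLP evaluation."""

    flow: dict
    baseline: pd.DataFrame
    yearly_status: pd.DataFrame
    or_table: pd.DataFrame
    importance: pd.DataFrame
    nlp_report: dict
    fits: dict = field(default_factory=dict, repr=False)


def yearly_status_ratios(analysis_set: pd.DataFrame) -> pd.DataFrame:
    """Per calendar year: count and proportion of each smoking status.

    Proportions within a year sum to 1; years without surgeries are
    omitted.
    """
    frame = analysis_set.copy()
    frame["year"] = pd.to_datetime(frame["date"]).dt.year
    counts = (
        frame.groupby(["year", "smoking_status"]).size().unstack(fill_value=0)
    )
    props = counts.div(counts.sum(axis=1), axis=0)
    out = counts.join(props, rsuffix="_prop")
    out["total"] = counts.sum(axis=1)
    return out


def _baseline_table(analysis: pd.DataFrame) -> pd.DataFrame:
    """Status-stratified baseline summary (counts, ages, ASA, CCI bands)."""
    rows = {}
    for status, grp in analysis.groupby("smoking_status"):
        rows[status] = {
            "n": len(grp),
            "age_median": grp["age_at_surgery"].median(),
            "age_iqr_low": grp["age_at_surgery"].quantile(0.25),
            "age_iqr_high": grp["age_at_surgery"].quantile(0.75),
            "male_pct": 100.0 * (grp["sex"] == "male").mean(),
            **{
                f"asa_{k}_pct": 100.0 * (grp["asa_class"] == k).mean()
                for k in range(1, 6)
            },
            **{
                f"cci_{band}_pct": 100.0 * (grp["cci_band"] == band).mean()
                for band in ["0", "1", "2", "3", "4", ">=5"]
            },
        }
    return pd.DataFrame(rows).T.rename_axis("smoking_status")


def run_study(config: RunConfig) -> StudyReport:
    """Execute every stage in order; deterministic given ``config.seed``."""
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # --- stage 1: simulate --------------------------------------------------
    sentences = generate_corpus(config.corpus)
    tables: CohortTables = generate_cohort(config.cohort)
    logger.info(
        "simulate: %d sentences, %d patients", len(sentences), len(tables.patients)
    )
    if out_dir:
        corpus_mod.write_corpus_jsonl(sentences, out_dir / "corpus.jsonl")
        write_registry(tables, out_dir / "registry")

    # --- stage 2: train + tune the classifier -------------------------------
    candidates = nlp.extract_candidate_sentences(sentences)
    known_unk = [s for s in sentences if not nlp.has_smoking_stem(
        nlp.normalize_text(s.text))]
    train_pool, test_set = nlp.split_corpus(
        candidates, test_fraction=0.10, seed=config.nlp_train.seed
    )
    train_set, tune_set = nlp.split_corpus(
        train_pool, test_fraction=0.10, seed=config.nlp_train.seed + 1
    )
    model = nlp.train_classifier(train_set, config.nlp_train)
    policy = nlp.tune_thresholds(
        model, tune_set, config.min_precision_known, config.grid_step
    )
    probs, _ = nlp.predict_proba(model, [s.text for s in test_set])
    predicted = nlp.threshold_labels(probs, policy)
    report = nlp.evaluate([s.label for s in test_set], list(predicted))
    logger.info(
        "nlp: %d train / %d tune / %d test (+%d without stems), accuracy %.3f",
        len(train_set), len(tune_set), len(test_set), len(known_unk),
        report.accuracy.estimate,
    )
    nlp_report = {
        "policy": {"current": policy.current, "ex": policy.ex,
                   "never": policy.never},
        "evaluation": report.to_dict(),
    }

    # --- stage 3: classify status notes -------------------------------------
    rng = np.random.default_rng(config.cohort.seed + 1)
    notes = tables.status_notes.copy()
    notes["text"] = [
        render_sentence(st, rng, noise_rate=config.corpus.noise_rate)
        for st in notes["status"]
    ]
    note_probs, _ = nlp.predict_proba(model, notes["text"].tolist())
    notes["predicted"] = nlp.threshold_labels(note_probs, policy)
    observations = notes[notes["predicted"] != "unknown"][
        ["patient_id", "date", "predicted"]
    ].rename(columns={"predicted": "status"})
    logger.info(
        "classify: %d notes -> %d usable observations", len(notes), len(observations)
    )

    # --- stage 4: assign + exclusions ---------------------------------------
    surgeries = tables.surgeries.merge(
        tables.patients[["patient_id", "sex", "true_status"]], on="patient_id"
    )
    statuses = assign_statuses(observations, surgeries)
    analysis, flow = build_analysis_set(surgeries, statuses)
    logger.info("assign: flow %s", flow)

    # --- stage 5: comorbidity + outcomes ------------------------------------
    cci = cci_table(tables.diagnosis_events, analysis)
    analysis = analysis.drop(columns=["cci_count", "cci_band"]).merge(
        cci, on="surgery_id"
    )
    overall_def, critical_def = default_definitions()
    overall = flag_outcomes(
        analysis, tables.diagnosis_events, tables.care_events, overall_def
    )
    critical = flag_outcomes(
        analysis, tables.diagnosis_events, tables.care_events, critical_def
    )
    analysis = analysis.set_index("surgery_id")
    analysis["overall"] = overall
    analysis["critical"] = critical
    analysis = analysis.reset_index()
    logger.info(
        "score: overall rate %.3f, critical rate %.3f",
        analysis["overall"].mean(), analysis["critical"].mean(),
    )

    # --- stage 6: analyze ----------------------------------------------------
    or_rows = []
    importance_rows = []
    fits = {}
    model_groups = [("all", analysis, ("overall", "critical"))]
    spec_counts = analysis["specialty"].value_counts()
    for specialty, count in spec_counts.items():
        if count > config.min_surgeries_per_specialty:
            model_groups.append(
                (specialty, analysis[analysis["specialty"] == specialty],
                 ("overall",))
            )

    for group_name, base_frame, outcome_names in model_groups:
        for outcome_name in outcome_names:
            y = base_frame[outcome_name].to_numpy()
            # sparse upper ASA/CCI bands are merged downward to avoid
            # separation in small samples / specialty subsets
            frame = base_frame.assign(
                cci_band=collapse_sparse_levels(
                    base_frame["cci_band"], y, ["0", "1", "2", "3", "4", ">=5"]
                ).to_numpy(),
                asa_class=collapse_sparse_levels(
                    base_frame["asa_class"].astype(str), y, ["1", "2", "3", "4", "5"]
                ).to_numpy(),
            )
            unadj = unadjusted_or_table(frame, y)
            spec = default_model_spec(outcome=outcome_name, adjusted=True)
            fit = fit_logistic(frame, y, spec)
            adj = fit.odds_ratios().loc[fit.groups["smoking_status"]]
            for level in unadj.index:
                row = unadj.loc[level]
                or_rows.append(
                    (group_name, outcome_name, level, "unadjusted",
                     row["odds_ratio"], row["ci_low"], row["ci_high"])
                )
            for col in adj.index:
                level = col.split("[", 1)[1].rstrip("]")
                or_rows.append(
                    (group_name, outcome_name, level, "adjusted",
                     adj.loc[col, "odds_ratio"], adj.loc[col, "ci_low"],
                     adj.loc[col, "ci_high"])
                )
            imp = importance_report(fit)
            for var, r in imp.table.iterrows():
                importance_rows.append(
                    (group_name, outcome_name, var, r["chisq"], r["share_pct"],
                     r["mean_abs_shapley"], imp.mcfadden, imp.nagelkerke)
                )
            fits[(group_name, outcome_name)] = fit

    or_table = pd.DataFrame(
        or_rows,
        columns=["group", "outcome", "smoking_status", "model",
                 "odds_ratio", "ci_low", "ci_high"],
    )
    importance = pd.DataFrame(
        importance_rows,
        columns=["group", "outcome", "variable", "wald_chisq", "wald_share_pct",
                 "mean_abs_shapley", "mcfadden_r2", "nagelkerke_r2"],
    )
    baseline = _baseline_table(analysis)
    yearly = yearly_status_ratios(analysis)

    report = StudyReport(
        flow=flow,
        baseline=baseline,
        yearly_status=yearly,
        or_table=or_table,
        importance=importance,
        nlp_report=nlp_report,
        fits=fits,
    )
    if out_dir:
        _write_report(report, analysis, out_dir)
    return report


def _write_report(report: StudyReport, analysis: pd.DataFrame, out_dir: Path):
    analysis.to_csv(out_dir / "analysis_set.csv", index=False)
    report.baseline.round(6).to_csv(out_dir / "baseline_table.csv")
    report.yearly_status.round(6).to_csv(out_dir / "yearly_status.csv")
    report.or_table.round(6).to_csv(out_dir / "or_table.csv", index=False)
    report.importance.round(6).to_csv(out_dir / "importance_table.csv", index=False)
    with open(out_dir / "flow.json", "w") as fh:
        json.dump(report.flow, fh, indent=2, sort_keys=True)
    with open(out_dir / "nlp_report.json", "w") as fh:
        json.dump(report.nlp_report, fh, indent=2, sort_keys=True)
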