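"""Simulation-study helpers: parameter recovery and NLP precision checks.

These drive the package's own validation experiments: generate a cohort
with known conditional odds ratios, refit the adjusted and unadjusted
models, and summarize coverage of the configured truth across seeds; and
train/tune the classifier on fresh synthetic corpora to measure the tuned
policy's held-out precision.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import nlp
from .cohort import CohortConfig, generate_cohort
from .corpus import CorpusConfig, generate_corpus
from .outcomes import default_definitions, flag_outcomes
from .stats import (
    collapse_sparse_levels,
    default_model_spec,
    fit_logistic,
    unadjusted_or_table,
)


def _seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def recover_conditional_ors(
    config: CohortConfig | None = None,
    n_seeds: int = 100,
    master_seed: int = 0,
) -> dict:
    """Coverage of the configured conditional ORs by the adjusted fit.

    For each seed: generate a cohort, flag overall complications, fit the
    adjusted logistic model on the generator's covariates, and record
    whether the 95% CI of each smoking coefficient covers the configured
    truth; also record the unadjusted (crude) ex-smoker OR.  Returns
    per-status coverage counts, mean adjusted ORs and the mean crude
    ex-smoker OR.
    """
    base = config or CohortConfig()
    truth = {"ex": base.conditional_or_overall[0],
             "current": base.conditional_or_overall[1]}
    overall_def, _ = default_definitions()
    spec = default_model_spec(outcome="overall", adjusted=True)

    covered = {"ex": 0, "current": 0}
    adjusted = {"ex": [], "current": []}
    crude_ex = []
    for seed in _seeds(master_seed, n_seeds):
        tables = generate_cohort(replace(base, seed=seed))
        flags = flag_outcomes(
            tables.surgeries, tables.diagnosis_events, tables.care_events,
            overall_def,
        )
        surg = tables.surgeries.merge(
            tables.patients[["patient_id", "sex", "true_status"]], on="patient_id"
        ).set_index("surgery_id")
        y = flags.loc[surg.index].to_numpy()
        frame = surg.assign(
            smoking_status=surg["true_status"],
            asa_class=collapse_sparse_levels(
                surg["asa_class"].astype(str), y, ["1", "2", "3", "4", "5"]
            ).to_numpy(),
            cci_band=collapse_sparse_levels(
                surg["cci_band"], y, ["0", "1", "2", "3", "4", ">=5"]
            ).to_numpy(),
        ).reset_index()
        fit = fit_logistic(frame, y, spec, keep_design=False)
        ors = fit.odds_ratios()
        for status in ("ex", "current"):
            row = ors.loc[f"smoking_status[{status}]"]
            adjusted[status].append(row["odds_ratio"])
            if row["ci_low"] <= truth[status] <= row["ci_high"]:
                covered[status] += 1
        crude_ex.append(
            unadjusted_or_table(frame, y).loc["ex", "odds_ratio"]
        )
    return {
        "n_seeds": n_seeds,
        "n_patients": base.n_patients,
        "truth": truth,
        "covered": covered,
        "mean_adjusted_or": {k: float(np.mean(v)) for k, v in adjusted.items()},
        "mean_crude_or_ex": float(np.mean(crude_ex)),
    }


def tuned_policy_heldout_metrics(
    corpus_config: CorpusConfig | None = None,
    train_config: nlp.TrainConfig | None = None,
    min_precision_known: float = 0.95,
    seed: int = 0,
) -> dict:
    """Train, tune and score the abstaining classifier on one fresh corpus.

    The corpus is split train/tune/held-out (81/9/10); thresholds are tuned
    on the tune split and all metrics are measured on the held-out split.
    """
    c_seed, t_seed = _seeds(seed, 2)
    ccfg = replace(corpus_config or CorpusConfig(), seed=c_seed)
    tcfg = replace(train_config or nlp.TrainConfig(), seed=t_seed)
    corpus = generate_corpus(ccfg)
    train_pool, heldout = nlp.split_corpus(corpus, 0.10, seed=t_seed)
    train, tune = nlp.split_corpus(train_pool, 0.10, seed=t_seed + 1)
    model = nlp.train_classifier(train, tcfg)
    policy = nlp.tune_thresholds(model, tune, min_precision_known)
    probs, _ = nlp.predict_proba(model, [s.text for s in heldout])
    raw_pred = [nlp.CLASS_ORDER[i] for i in probs.argmax(axis=1)]
    pred = list(nlp.threshold_labels(probs, policy))
    gold = [s.label for s in heldout]
    report = nlp.evaluate(gold, pred)
    raw_report = nlp.evaluate(gold, raw_pred)
    precisions = {
        c: (report.precision[c].estimate if report.precision[c] else None)
        for c in nlp.KNOWN_CLASSES
    }
    n_pred = {
        c: int(report.confusion[c].sum()) for c in nlp.KNOWN_CLASSES
    }
    return {
        "policy": policy,
        "raw_accuracy": raw_report.accuracy.estimate,
        "accuracy": report.accuracy.estimate,
        "precision_known": precisions,
        "n_predicted": n_pred,
        "macro_precision_known": report.macro_precision_known,
        "n_heldout": report.n,
    }
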