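"""Text normalization, classifier, abstention thresholds and evaluation."""

import itertools
from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smokesurg import nlp
from smokesurg.nlp import (
    CLASS_ORDER,
    ClassDistribution,
    LabeledSentence,
    ThresholdPolicy,
    TrainConfig,
    apply_threshold_policy,
    cross_validate,
    evaluate,
    extract_candidate_sentences,
    normalize_text,
    predict,
    threshold_labels,
    train_classifier,
    tune_thresholds_from_scores,
    wald_proportion_ci,
)

# ---------------------------------------------------------------------------
# normalization and stem filtering


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("Tupakointi: 10 ask./v!!", "tupakointi 10 ask v"),
        ("", ""),
        ("  EI   tupakoi.  ", "ei tupakoi"),
        ("päivässä Äiti ÅSA", "päivässä äiti åsa"),
    ],
)
def test_normalize_examples(raw, expected):
    assert normalize_text(raw) == expected


@settings(max_examples=200, deadline=None)
@given(st.text(max_size=80))
def test_normalize_idempotent_and_clean(text):
    once = normalize_text(text)
    assert normalize_text(once) == once
    assert "  " not in once
    assert once == once.lower()


def _sent(text, label=None):
    return LabeledSentence("p1", date(2018, 1, 1), text, label)


def test_stem_filter_keeps_exactly_stem_sentences():
    kept = extract_candidate_sentences(
        [
            _sent("potilas tupakoi paivittain"),
            _sent("ei loydoksia"),
            _sent("smoking status unknown"),
            _sent("ASKI kuluu paivassa"),
            _sent("paskainen ei kelpaa"),  # stem must start the token
        ]
    )
    assert [s.text for s in kept] == [
        "potilas tupakoi paivittain",
        "smoking status unknown",
        "ASKI kuluu paivassa",
    ]


# ---------------------------------------------------------------------------
# training and prediction


def _toy_separable_corpus(n=200):
    texts = {
        "current": "polttaa paljon nyt",
        "ex": "lopetti kauan sitten",
        "never": "raitis koko ikansa",
        "unknown": "tieto puuttuu kokonaan",
    }
    labels = [CLASS_ORDER[i % 4] for i in range(n)]
    return [_sent(texts[lab], lab) for lab in labels]


def test_separable_toy_reaches_training_accuracy_one():
    corpus = _toy_separable_corpus()
    model = train_classifier(corpus, TrainConfig(epochs=5, seed=0))
    preds = [
        CLASS_ORDER[int(np.argmax(predict(model, s.text).probs))] for s in corpus
    ]
    assert preds == [s.label for s in corpus]


def test_training_is_deterministic():
    corpus = _toy_separable_corpus(80)
    cfg = TrainConfig(epochs=3, seed=7)
    m1 = train_classifier(corpus, cfg)
    m2 = train_classifier(corpus, cfg)
    assert np.array_equal(m1.class_weights, m2.class_weights)
    assert np.array_equal(m1.embeddings, m2.embeddings)


def test_missing_label_raises():
    corpus = [_sent("tupakoi", "current"), _sent("ei tupakoi", "never")]
    with pytest.raises(ValueError, match="lacks label"):
        train_classifier(corpus, TrainConfig(epochs=1))


def test_heldout_accuracy_on_synthetic_corpus(trained_model):
    model, _, test = trained_model
    probs, _ = nlp.predict_proba(model, [s.text for s in test])
    acc = np.mean(
        [CLASS_ORDER[i] == s.label for i, s in zip(probs.argmax(1), test)]
    )
    assert acc > 0.85


def test_predict_distribution_properties(trained_model):
    model, _, _ = trained_model
    d1 = predict(model, "tupakoi edelleen paljon")
    d2 = predict(model, "tupakoi edelleen paljon")
    assert abs(d1.probs.sum() - 1.0) < 1e-9
    assert np.array_equal(d1.probs, d2.probs)
    empty = predict(model, "!!!")
    assert empty.uniform_fallback
    assert np.allclose(empty.probs, 0.25)


def test_model_roundtrip_serialization(trained_model, tmp_path):
    model, _, _ = trained_model
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = nlp.TextClassifierModel.load(path)
    assert loaded.config == model.config
    assert np.array_equal(loaded.class_weights, model.class_weights)
    d = predict(loaded, "lopettanut tupakoinnin 3 20")
    assert abs(d.probs.sum() - 1.0) < 1e-9


# ---------------------------------------------------------------------------
# threshold policy


def _dist(p):
    return ClassDistribution(np.asarray(p, dtype=float))


@pytest.mark.parametrize(
    "probs,policy,expected",
    [
        ((0.92, 0.04, 0.02, 0.02), ThresholdPolicy(0.8, 0.5, 0.5), "current"),
        ((0.60, 0.20, 0.10, 0.10), ThresholdPolicy(0.8, 0.5, 0.5), "unknown"),
        ((0.10, 0.10, 0.10, 0.70), ThresholdPolicy(0.0, 0.0, 0.0), "unknown"),
        ((0.25, 0.25, 0.25, 0.25), ThresholdPolicy(0.0, 0.0, 0.0), "current"),
    ],
)
def test_threshold_policy_examples(probs, policy, expected):
    # last case: exact tie resolves to the class earliest in CLASS_ORDER
    assert apply_threshold_policy(_dist(probs), policy) == expected


def test_threshold_out_of_range_rejected():
    with pytest.raises(ValueError):
        ThresholdPolicy(1.2, 0.0, 0.0)


def test_abstention_monotone_in_thresholds():
    rng = np.random.default_rng(0)
    raw = rng.dirichlet(np.ones(4), size=400)
    grid = [0.0, 0.3, 0.6, 0.9]
    for cls_i, cls in enumerate(("current", "ex", "never")):
        prev_sets = None
        for theta in grid:
            kwargs = {"current": 0.2, "ex": 0.2, "never": 0.2}
            kwargs[cls] = theta
            labels = threshold_labels(raw, ThresholdPolicy(**kwargs))
            assigned = set(np.flatnonzero(labels == cls))
            if prev_sets is not None:
                assert assigned <= prev_sets  # retained set shrinks
            prev_sets = assigned


# 12 hand-listed (distribution, gold) validation pairs for tuning
_TOY_VALIDATION = [
    ((0.90, 0.05, 0.03, 0.02), "current"),
    ((0.80, 0.10, 0.05, 0.05), "current"),
    ((0.55, 0.25, 0.10, 0.10), "ex"),  # current argmax, wrong
    ((0.05, 0.85, 0.05, 0.05), "ex"),
    ((0.10, 0.60, 0.20, 0.10), "ex"),
    ((0.15, 0.55, 0.20, 0.10), "never"),  # ex argmax, wrong
    ((0.02, 0.03, 0.90, 0.05), "never"),
    ((0.05, 0.05, 0.70, 0.20), "never"),
    ((0.10, 0.10, 0.45, 0.35), "current"),  # never argmax, wrong
    ((0.05, 0.05, 0.10, 0.80), "unknown"),
    ((0.20, 0.20, 0.20, 0.40), "unknown"),
    ((0.85, 0.05, 0.05, 0.05), "unknown"),  # confident but wrong
]


def _oracle_grid_search(pairs, min_precision, grid_step):
    """Exhaustive enumeration over the full 3-D threshold grid."""
    probs = np.array([p for p, _ in pairs])
    gold = np.array([g for _, g in pairs], dtype=object)
    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    best = None
    for triple in itertools.product(grid, repeat=3):
        policy = ThresholdPolicy(*triple)
        pred = threshold_labels(probs, policy)
        feasible = True
        objective = 0.0
        for cls in ("current", "ex", "never"):
            retained = pred == cls
            n_ret = retained.sum()
            n_cor = (retained & (gold == cls)).sum()
            if n_ret and n_cor / n_ret < min_precision - 1e-12:
                feasible = False
                break
            n_gold = (gold == cls).sum()
            objective += n_cor / n_gold if n_gold else 0.0
        if not feasible:
            continue
        key = (-objective, triple)
        if best is None or key < best[0]:
            best = (key, policy)
    return best[1] if best else ThresholdPolicy(1.0, 1.0, 1.0)


@pytest.mark.parametrize("min_precision", [0.0, 0.6, 0.9, 1.0])
def test_tuned_thresholds_match_exhaustive_grid_search(min_precision):
    probs = np.array([p for p, _ in _TOY_VALIDATION])
    gold = [g for _, g in _TOY_VALIDATION]
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        got = tune_thresholds_from_scores(probs, gold, min_precision, grid_step=0.25)
    expected = _oracle_grid_search(_TOY_VALIDATION, min_precision, 0.25)
    assert got == expected


def test_unconstrained_tuning_gives_zero_thresholds():
    probs = np.array([p for p, _ in _TOY_VALIDATION])
    gold = [g for _, g in _TOY_VALIDATION]
    assert tune_thresholds_from_scores(probs, gold, 0.0, 0.25) == ThresholdPolicy(
        0.0, 0.0, 0.0
    )


def test_infeasible_tuning_abstains_everywhere_with_warning():
    # classifier errs on every prediction of every known class
    probs = np.array([(0.9, 0.04, 0.03, 0.03)] * 6)
    gold = ["ex"] * 6
    with pytest.warns(UserWarning, match="infeasible"):
        policy = tune_thresholds_from_scores(probs, gold, 1.0, 0.25)
    assert policy == ThresholdPolicy(1.0, 1.0, 1.0)


# ---------------------------------------------------------------------------
# evaluation


def test_perfect_predictions():
    gold = ["current", "ex", "never", "unknown"] * 5
    rep = evaluate(gold, gold)
    assert rep.accuracy.estimate == 1.0
    for cls in CLASS_ORDER:
        assert rep.precision[cls].estimate == 1.0
        assert rep.recall[cls].estimate == 1.0
    assert rep.macro_precision_known == 1.0


def test_wald_ci_closed_form():
    ci = wald_proportion_ci(0.9, 100)
    assert round(ci.ci_low, 3) == 0.841
    assert round(ci.ci_high, 3) == 0.959


def test_macro_precision_is_unweighted_mean():
    # 0.958 / 0.974 / 0.95 must average to 0.9607 (printed as 96.1%)
    vals = (0.958, 0.974, 0.95)
    assert round(float(np.mean(vals)) * 100, 1) == 96.1


def test_zero_denominator_metric_reported_absent():
    rep = evaluate(["current", "current"], ["never", "never"])
    assert rep.precision["current"] is None  # never predicted
    assert rep.recall["never"] is None  # never in gold
    assert rep.macro_precision_known is None


def test_evaluate_permutation_invariant():
    rng = np.random.default_rng(1)
    gold = rng.choice(CLASS_ORDER, 60).tolist()
    pred = rng.choice(CLASS_ORDER, 60).tolist()
    rep1 = evaluate(gold, pred)
    perm = rng.permutation(60)
    rep2 = evaluate([gold[i] for i in perm], [pred[i] for i in perm])
    assert rep1.confusion.equals(rep2.confusion)
    assert rep1.accuracy == rep2.accuracy


def test_confusion_trace_equals_accuracy():
    rng = np.random.default_rng(2)
    gold = rng.choice(CLASS_ORDER, 80).tolist()
    pred = rng.choice(CLASS_ORDER, 80).tolist()
    rep = evaluate(gold, pred)
    assert np.isclose(
        np.trace(rep.confusion.to_numpy()) / rep.n, rep.accuracy.estimate
    )


# ---------------------------------------------------------------------------
# cross-validation


def _cv_corpus(n=100):
    rng = np.random.default_rng(5)
    from smokesurg.corpus import render_sentence

    labels = [CLASS_ORDER[i % 4] for i in range(n)]
    return [_sent(render_sentence(lab, rng), lab) for lab in labels]


def test_cross_validation_partitions_and_pools():
    corpus = _cv_corpus(100)
    cfg = TrainConfig(epochs=2, seed=3)
    res = cross_validate(corpus, k=5, train_config=cfg)
    assert len(res.fold_reports) == 5
    sizes = [r.n for r in res.fold_reports]
    assert sizes == [20] * 5
    pooled_conf = sum(r.confusion.to_numpy() for r in res.fold_reports)
    assert np.array_equal(pooled_conf, res.pooled.confusion.to_numpy())
    assert res.pooled.n == 100

    res2 = cross_validate(corpus, k=5, train_config=cfg)
    for a, b in zip(res.fold_reports, res2.fold_reports):
        assert a.confusion.equals(b.confusion)  # deterministic folds


def test_cross_validation_input_checks():
    corpus = _cv_corpus(12)
    with pytest.raises(ValueError):
        cross_validate(corpus, k=1)
    with pytest.raises(ValueError):
        cross_validate(corpus[:3], k=5)
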