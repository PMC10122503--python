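"""Smoking-status classification of clinical free-text sentences.

Sentences are lower-cased, stripped of special characters, filtered on the
Finnish/English smoking word stems (``tupak*``, ``aski*``, ``smok*``) and
classified into four classes — current smoker, ex-smoker, never-smoker,
unknown — by a linear bag-of-n-grams model: hashed unigram+bigram
embeddings are averaged and fed to a linear softmax layer trained by SGD
(the fastText recipe, reimplemented in numpy so every step is inspectable).

The *unknown* class doubles as an abstention sink: after training,
per-class probability thresholds reroute low-confidence predictions of the
three known classes to unknown.  Thresholds are tuned on labeled validation
data by maximizing total retained known-class recall subject to every known
class reaching a minimum precision (default 0.95) — the "tuned in favour of
specificity" policy formalized as a constrained grid search.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

logger = logging.getLogger(__name__)

CLASS_ORDER: tuple[str, ...] = ("current", "ex", "never", "unknown")
KNOWN_CLASSES: tuple[str, ...] = ("current", "ex", "never")
SMOKING_STEMS: tuple[str, ...] = ("tupak", "aski", "smok")

_CLASS_INDEX = {c: i for i, c in enumerate(CLASS_ORDER)}

# characters surviving normalization: ascii letters, Finnish å/ä/ö, digits, space
_KEEP = frozenset("abcdefghijklmnopqrstuvwxyzåäö0123456789 ")


@dataclass(frozen=True)
class LabeledSentence:
    """One timestamped smoking-related free-text sentence."""

    patient_id: str
    timestamp: date
    text: str
    label: str | None = None  # one of CLASS_ORDER, or None when unannotated


def normalize_text(text: str) -> str:
    """Lower-case, drop special characters, collapse whitespace (idempotent)."""
    lowered = text.lower()
    cleaned = "".join(ch if ch in _KEEP else " " for ch in lowered)
    return " ".join(cleaned.split())


def has_smoking_stem(normalized_text: str) -> bool:
    return any(
        tok.startswith(stem)
        for tok in normalized_text.split()
        for stem in SMOKING_STEMS
    )


def extract_candidate_sentences(
    sentences: Iterable[LabeledSentence],
) -> list[LabeledSentence]:
    """Keep exactly the sentences containing a smoking word stem."""
    return [s for s in sentences if has_smoking_stem(normalize_text(s.text))]


# ---------------------------------------------------------------------------
# hashed n-gram features

_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3
_MASK64 = 0xFFFFFFFFFFFFFFFF


def _fnv1a(data: bytes) -> int:
    h = _FNV_OFFSET
    for b in data:
        h = ((h ^ b) * _FNV_PRIME) & _MASK64
    return h


def hash_features(normalized_text: str, ngram_order: int, buckets: int) -> np.ndarray:
    """Bucket indices of all 1..ngram_order token n-grams (with repeats)."""
    tokens = normalized_text.split()
    idx = []
    for n in range(1, ngram_order + 1):
        for i in range(len(tokens) - n + 1):
            gram = " ".join(tokens[i : i + n])
            idx.append(_fnv1a(gram.encode("utf-8")) % buckets)
    return np.asarray(idx, dtype=np.int64)


# ---------------------------------------------------------------------------
# model

@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 10
    learning_rate: float = 0.1
    hash_buckets: int = 2**18
    embedding_dim: int = 32
    ngram_order: int = 2
    seed: int = 0


@dataclass
class TextClassifierModel:
    """Averaged hashed n-gram embeddings -> linear softmax over four classes."""

    embeddings: np.ndarray  # (hash_buckets, embedding_dim) float32
    class_weights: np.ndarray  # (4, embedding_dim) float32
    config: TrainConfig
    class_order: tuple[str, ...] = CLASS_ORDER
    epoch_losses: tuple[float, ...] = field(default=())

    def save(self, path) -> None:
        """Single-file binary serialization with an embedded config header."""
        np.savez(
            path,
            embeddings=self.embeddings,
            class_weights=self.class_weights,
            header=np.frombuffer(
                json.dumps(
                    {"config": self.config.__dict__, "class_order": self.class_order}
                ).encode("utf-8"),
                dtype=np.uint8,
            ),
        )

    @classmethod
    def load(cls, path) -> "TextClassifierModel":
        with np.load(path) as data:
            header = json.loads(bytes(data["header"].tobytes()).decode("utf-8"))
            return cls(
                embeddings=data["embeddings"],
                class_weights=data["class_weights"],
                config=TrainConfig(**header["config"]),
                class_order=tuple(header["class_order"]),
            )


class ClassDistribution(NamedTuple):
    """Per-class probabilities in CLASS_ORDER; flags the no-feature fallback."""

    probs: np.ndarray  # shape (4,), sums to 1
    uniform_fallback: bool = False


def _softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def train_classifier(
    corpus: Sequence[LabeledSentence], train_config: TrainConfig | None = None
) -> TextClassifierModel:
    """Fit the classifier by SGD on softmax cross-entropy.

    The learning rate decays linearly to zero over all updates; sentence
    order is reshuffled each epoch from the config seed, so training is
    deterministic.  Raises ``ValueError`` if any of the four classes is
    absent from the training corpus.
    """
    cfg = train_config or TrainConfig()
    labels = [s.label for s in corpus]
    missing = set(CLASS_ORDER) - set(labels)
    if missing:
        raise ValueError(f"training corpus lacks label(s): {sorted(missing)}")

    rng = np.random.default_rng(cfg.seed)
    feats = [
        hash_features(normalize_text(s.text), cfg.ngram_order, cfg.hash_buckets)
        for s in corpus
    ]
    y = np.array([_CLASS_INDEX[lab] for lab in labels], dtype=np.int64)

    emb = rng.uniform(
        -1.0 / cfg.embedding_dim,
        1.0 / cfg.embedding_dim,
        size=(cfg.hash_buckets, cfg.embedding_dim),
    ).astype(np.float32)
    weights = np.zeros((len(CLASS_ORDER), cfg.embedding_dim), dtype=np.float32)

    n = len(corpus)
    total = cfg.epochs * n
    step = 0
    losses = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        loss_sum = 0.0
        for i in order:
            idx = feats[i]
            lr = cfg.learning_rate * (1.0 - step / total)
            step += 1
            if idx.size == 0:
                continue
            h = emb[idx].mean(axis=0)
            p = _softmax(weights @ h)
            loss_sum -= float(np.log(max(p[y[i]], 1e-12)))
            g = p.copy()
            g[y[i]] -= 1.0
            grad_h = weights.T @ g
            weights -= lr * np.outer(g, h)
            np.add.at(emb, idx, (-lr / idx.size) * grad_h)
        losses.append(loss_sum / n)
        logger.debug("epoch %d mean loss %.4f", epoch, losses[-1])
    return TextClassifierModel(
        embeddings=emb,
        class_weights=weights,
        config=cfg,
        epoch_losses=tuple(losses),
    )


def predict(model: TextClassifierModel, text: str) -> ClassDistribution:
    """Class probabilities for one sentence (normalizes internally).

    A sentence with no tokens after normalization has no features and maps
    to the uniform distribution, flagged via ``uniform_fallback``.
    """
    cfg = model.config
    idx = hash_features(normalize_text(text), cfg.ngram_order, cfg.hash_buckets)
    if idx.size == 0:
        k = len(model.class_order)
        return ClassDistribution(np.full(k, 1.0 / k), uniform_fallback=True)
    h = model.embeddings[idx].mean(axis=0, dtype=np.float64)
    scores = model.class_weights.astype(np.float64) @ h
    return ClassDistribution(_softmax(scores))


def predict_proba(
    model: TextClassifierModel, texts: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Batch probabilities: (n, 4) array plus boolean fallback flags."""
    out = np.empty((len(texts), len(model.class_order)))
    flags = np.zeros(len(texts), dtype=bool)
    for i, t in enumerate(texts):
        dist = predict(model, t)
        out[i] = dist.probs
        flags[i] = dist.uniform_fallback
    return out, flags


# ---------------------------------------------------------------------------
# abstention thresholds

@dataclass(frozen=True)
class ThresholdPolicy:
    """Per-known-class minimum probabilities; below them the prediction abstains."""

    current: float = 0.0
    ex: float = 0.0
    never: float = 0.0

    def __post_init__(self):
        for name in ("current", "ex", "never"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"threshold {name}={v} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.current, self.ex, self.never])


def apply_threshold_policy(dist: ClassDistribution, policy: ThresholdPolicy) -> str:
    """Argmax label if it is a known class clearing its threshold, else unknown.

    Exact probability ties resolve to the class earlier in CLASS_ORDER.
    """
    probs = np.asarray(dist.probs if isinstance(dist, ClassDistribution) else dist)
    top = int(np.argmax(probs))
    if top >= len(KNOWN_CLASSES):
        return "unknown"
    if probs[top] >= policy.as_array()[top]:
        return CLASS_ORDER[top]
    return "unknown"


def threshold_labels(probs: np.ndarray, policy: ThresholdPolicy) -> np.ndarray:
    """Vectorized apply_threshold_policy over an (n, 4) probability array."""
    top = probs.argmax(axis=1)
    pmax = probs[np.arange(len(probs)), top]
    theta = np.append(policy.as_array(), 0.0)
    keep = (top < len(KNOWN_CLASSES)) & (pmax >= theta[top])
    out = np.where(keep, top, _CLASS_INDEX["unknown"])
    return np.array(CLASS_ORDER, dtype=object)[out]


def tune_thresholds_from_scores(
    probs: np.ndarray,
    gold_labels: Sequence[str],
    min_precision_known: float = 0.95,
    grid_step: float = 0.05,
) -> ThresholdPolicy:
    """Grid-search the threshold triple on precomputed probabilities.

    Maximizes the total retained recall of the three known classes subject
    to each known class's retained precision >= ``min_precision_known``
    (classes retaining nothing satisfy the constraint vacuously); ties break
    toward lower thresholds.  Because each class's precision and recall
    depend only on its own threshold, the 3-D search decomposes exactly
    into three 1-D scans (verified against exhaustive enumeration in the
    test suite).  If some class admits no feasible threshold that retains
    anything, the all-abstain policy (1, 1, 1) is returned with a warning.
    """
    probs = np.asarray(probs, dtype=float)
    gold = np.asarray(gold_labels, dtype=object)
    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    top = probs.argmax(axis=1)

    chosen: dict[str, float] = {}
    predicted_classes = 0
    infeasible_classes = 0
    for ci, cls in enumerate(KNOWN_CLASSES):
        cand = top == ci
        p_top = probs[cand, ci]
        correct = gold[cand] == cls
        n_gold = int((gold == cls).sum())
        best_recall, best_theta, any_retaining_feasible = -1.0, 1.0, False
        for theta in grid:
            retained = p_top >= theta
            n_ret = int(retained.sum())
            n_cor = int(correct[retained].sum())
            # a threshold retaining nothing satisfies the constraint vacuously
            feasible = n_ret == 0 or n_cor / n_ret >= min_precision_known - 1e-12
            if not feasible:
                continue
            if n_ret > 0:
                any_retaining_feasible = True
            recall = n_cor / n_gold if n_gold else 0.0
            if recall > best_recall + 1e-15:
                best_recall, best_theta = recall, float(theta)
        if cand.any():
            predicted_classes += 1
            if not any_retaining_feasible:
                infeasible_classes += 1
        chosen[cls] = best_theta

    if infeasible_classes:
        warnings.warn(
            "precision constraint infeasible (retains nothing) for "
            f"{infeasible_classes} class(es)",
            stacklevel=2,
        )
        if infeasible_classes == predicted_classes:
            # nothing can ever be retained: the all-abstain policy
            return ThresholdPolicy(1.0, 1.0, 1.0)
    return ThresholdPolicy(**chosen)


def tune_thresholds(
    model: TextClassifierModel,
    validation_corpus: Sequence[LabeledSentence],
    min_precision_known: float = 0.95,
    grid_step: float = 0.05,
) -> ThresholdPolicy:
    """Tune the abstention thresholds on a labeled validation corpus."""
    probs, _ = predict_proba(model, [s.text for s in validation_corpus])
    gold = [s.label for s in validation_corpus]
    return tune_thresholds_from_scores(probs, gold, min_precision_known, grid_step)


# ---------------------------------------------------------------------------
# evaluation

class MetricCI(NamedTuple):
    estimate: float
    ci_low: float
    ci_high: float


def wald_proportion_ci(p: float, n: int, z: float = 1.96) -> MetricCI:
    """Normal-approximation 95% CI for a proportion: p ± z·√(p(1−p)/n)."""
    half = z * float(np.sqrt(p * (1.0 - p) / n))
    return MetricCI(p, max(0.0, p - half), min(1.0, p + half))


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion matrix (rows gold, columns predicted) and derived metrics.

    ``precision``/``recall`` map class name to a MetricCI, or None when the
    denominator is zero (a metric is reported absent, never as 0).  Macro
    averages are unweighted means over the three known classes; the
    support-weighted known-class recall is reported alongside.
    """

    confusion: pd.DataFrame
    precision: dict
    recall: dict
    accuracy: MetricCI
    macro_precision_known: float | None
    macro_recall_known: float | None
    weighted_recall_known: float | None
    n: int

    def to_dict(self) -> dict:
        def metric(m):
            return None if m is None else {"estimate": m.estimate,
                                           "ci_low": m.ci_low, "ci_high": m.ci_high}

        return {
            "n": self.n,
            "confusion": self.confusion.to_dict(),
            "precision": {c: metric(m) for c, m in self.precision.items()},
            "recall": {c: metric(m) for c, m in self.recall.items()},
            "accuracy": metric(self.accuracy),
            "macro_precision_known": self.macro_precision_known,
            "macro_recall_known": self.macro_recall_known,
            "weighted_recall_known": self.weighted_recall_known,
        }


def evaluate(
    gold_labels: Sequence[str], predicted_labels: Sequence[str]
) -> EvaluationReport:
    """Per-class precision/recall with Wald 95% CIs, accuracy, macro averages."""
    gold = np.asarray(gold_labels, dtype=object)
    pred = np.asarray(predicted_labels, dtype=object)
    if gold.shape != pred.shape:
        raise ValueError("gold and predicted label sequences differ in length")

    confusion = pd.DataFrame(
        0, index=list(CLASS_ORDER), columns=list(CLASS_ORDER), dtype=int
    )
    for g, p in zip(gold, pred):
        confusion.loc[g, p] += 1

    precision: dict[str, MetricCI | None] = {}
    recall: dict[str, MetricCI | None] = {}
    for cls in CLASS_ORDER:
        tp = int(confusion.loc[cls, cls])
        n_pred = int(confusion[cls].sum())
        n_gold = int(confusion.loc[cls].sum())
        precision[cls] = wald_proportion_ci(tp / n_pred, n_pred) if n_pred else None
        recall[cls] = wald_proportion_ci(tp / n_gold, n_gold) if n_gold else None

    n = len(gold)
    accuracy = wald_proportion_ci(float((gold == pred).mean()), n)

    def _macro(metrics):
        vals = [metrics[c] for c in KNOWN_CLASSES]
        if any(v is None for v in vals):
            return None
        return float(np.mean([v.estimate for v in vals]))

    supports = np.array([int(confusion.loc[c].sum()) for c in KNOWN_CLASSES])
    recalls = [recall[c] for c in KNOWN_CLASSES]
    if supports.sum() and all(r is not None for r in recalls):
        weighted = float(
            np.average([r.estimate for r in recalls], weights=supports)
        )
    else:
        weighted = None

    return EvaluationReport(
        confusion=confusion,
        precision=precision,
        recall=recall,
        accuracy=accuracy,
        macro_precision_known=_macro(precision),
        macro_recall_known=_macro(recall),
        weighted_recall_known=weighted,
        n=n,
    )


# ---------------------------------------------------------------------------
# splits and cross-validation

def split_corpus(
    corpus: Sequence[LabeledSentence], test_fraction: float = 0.1, seed: int = 0
) -> tuple[list[LabeledSentence], list[LabeledSentence]]:
    """Stratified train/test split (default 90/10)."""
    labels = [s.label for s in corpus]
    train, test = train_test_split(
        list(corpus), test_size=test_fraction, stratify=labels, random_state=seed
    )
    return train, test


@dataclass(frozen=True)
class CrossValidationResult:
    fold_reports: tuple[EvaluationReport, ...]
    pooled: EvaluationReport


def cross_validate(
    corpus: Sequence[LabeledSentence],
    k: int = 5,
    train_config: TrainConfig | None = None,
) -> CrossValidationResult:
    """Stratified k-fold CV of the raw (unthresholded) classifier.

    Falls back to an unstratified split, with a log message, when some class
    has fewer than k members.  The pooled report concatenates all test-fold
    predictions, so its confusion matrix is the sum of the fold matrices.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(corpus) < k:
        raise ValueError("corpus smaller than the number of folds")
    cfg = train_config or TrainConfig()
    labels = np.array([s.label for s in corpus], dtype=object)
    counts = pd.Series(labels).value_counts()
    if (counts < k).any():
        logger.warning("class with < k members; falling back to plain k-fold")
        splitter = KFold(n_splits=k, shuffle=True, random_state=cfg.seed)
        splits = splitter.split(labels)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=cfg.seed)
        splits = splitter.split(labels, labels)

    fold_reports = []
    gold_all: list[str] = []
    pred_all: list[str] = []
    for train_idx, test_idx in splits:
        model = train_classifier([corpus[i] for i in train_idx], cfg)
        texts = [corpus[i].text for i in test_idx]
        probs, _ = predict_proba(model, texts)
        pred = [CLASS_ORDER[j] for j in probs.argmax(axis=1)]
        gold = [corpus[i].label for i in test_idx]
        fold_reports.append(evaluate(gold, pred))
        gold_all.extend(gold)
        pred_all.extend(pred)
    return CrossValidationResult(
        fold_reports=tuple(fold_reports), pooled=evaluate(gold_all, pred_all)
    )
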