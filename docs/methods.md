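# Methods

This note documents the models and procedures implemented in `smokesurg`,
the assumptions behind the synthetic-data generator, the numerical choices
made where the design was genuinely open, and what the package's tests do
and do not demonstrate about real data.

## Text classifier

**Model.** A sentence is normalized (lower case; every character outside
letters — including å/ä/ö — digits and spaces becomes a space; whitespace
collapsed) and represented by its token unigrams and bigrams, hashed by
64-bit FNV-1a into 2^18 buckets. Bucket embeddings (dimension 32, float32,
initialized uniform ±1/32) are averaged and passed through a linear layer
into a 4-class softmax over (current, ex, never, unknown). Training is
plain SGD on cross-entropy: 10 epochs, learning rate 0.1 decaying linearly
to zero over all updates, sentence order reshuffled per epoch from the
seed. All hyperparameters live in `TrainConfig`; none of them is tuned per
dataset — they are pinned for reproducibility. The architecture is the
standard fast linear text-classification recipe, reimplemented in numpy so
every step (hashing, averaging, gradients) is inspectable and exactly
reproducible.

A sentence with no tokens after normalization has no features; it receives
the uniform distribution and is flagged rather than silently classified.
Exact probability ties resolve to the class earliest in the fixed order
(current < ex < never < unknown); with float probabilities this is a
measure-zero event but the rule is deterministic.

**Abstention.** The unknown class is both a genuine label (e-cigarette
use, pack-year histories, undated quit notes) and an abstention sink.
After training, per-class thresholds θ_c ∈ [0,1] are tuned on a labeled
validation split: the argmax prediction c is kept iff c is a known class
and P(c) ≥ θ_c, otherwise the sentence is routed to unknown. The tuning
objective — the package's formalization of "tuned in favour of
specificity" — maximizes the sum of the three known-class recalls subject
to each known class's retained precision ≥ `min_precision_known` (default
0.95), over the grid θ ∈ {0, s, 2s, …, 1}³ (default step 0.05). A
threshold retaining nothing satisfies its constraint vacuously; ties break
toward lower thresholds. Because each class's precision and recall depend
only on its own threshold, the 3-D search decomposes into three 1-D scans;
the test suite verifies this equals exhaustive 3-D enumeration. If no
threshold can make some predicted class precise enough, and that is true
of every predicted class, the tuner returns the all-abstain policy
(1, 1, 1) with a warning.

**Evaluation.** Per-class precision TP/(TP+FP) and recall TP/(TP+FN) with
95% CIs by the normal (Wald) approximation p̂ ± 1.96·√(p̂(1−p̂)/n), n being
the metric's own denominator; overall accuracy over all four classes;
macro precision/recall as unweighted means over the three known classes
(the unknown class is an operating decision, not a target). A
support-weighted known-class recall is reported alongside the unweighted
one, since the two can differ materially when class supports are skewed
and published "average recall" figures do not always state their
weighting. Metrics with zero denominators are reported absent, never as 0.
Cross-validation is stratified k-fold (default 5) of the raw argmax
classifier; the pooled report concatenates test folds, so its confusion
matrix is the exact sum of the fold matrices.

## Status assignment

Observations (classified sentences with dates; unknowns already dropped)
collapse to one preoperative status per surgery: only observations dated
on or before the surgery count (admission-day notes are preoperative —
`≤`, not `<`); the most recent wins; but a most-recent *never* is
overridden to *ex* when any earlier observation says current or ex,
because a never-smoker note cannot erase documented smoking history. The
override is status-level, not pairwise: any earlier smoking evidence
triggers it. Same-day conflicts resolve by the precedence
current > ex > never, conservative toward detecting exposure. The rule is
order-invariant and ignores postoperative notes by construction; both
properties are enforced as tests, along with exhaustive enumeration over
all ≤3-observation histories.

The exclusion cascade (unknown status, age < 16, missing ASA class) is
applied in that order, each surgery counted once at its first failing
check, and emits a flow table whose counts reconcile exactly.

## Charlson comorbidity index

The ICD-10 → category mapping is the Quan coding with the original
Charlson weights, shipped as `data/charlson_quan_icd10.csv`
(category, prefix, weight, supersedes) so alternative weightings can be
swapped without code changes. Codes are matched prefix-wise after
upper-casing and dot removal ("I21.0" → "I210"); overlapping prefixes
resolve to the longest match. Hierarchy: metastatic solid tumour
supersedes any malignancy, moderate/severe liver disease supersedes mild,
complicated diabetes supersedes uncomplicated — a superseded category
contributes neither flag nor weight. Both the comorbidity *count* and the
*weighted score* are computed; the regression covariate defaults to the
count band {0,1,2,3,4,≥5}, since the baseline table this package mirrors
stratifies by the number of comorbidities. The lookback window for
diagnosis codes defaults to all history before surgery and is
configurable.

## Outcomes

A composite outcome is a set of ICD-10 prefixes plus a set of care-event
kinds with a follow-up window. The window is inclusive at both ends, days
0–90: surgery-day events are perioperative and day-90 events still count;
day 91 does not. The *overall* composite covers representative prefixes
for wound, cardiovascular, neurological, respiratory, thromboembolic,
gastroenterological, urinary and orthopaedic complications and unspecified
bacterial infections, plus all four care-event kinds (death, reoperation,
readmission, ICU admission or mechanical ventilation). The *critical*
composite (life-threatening complications and death) contains acute
coronary syndrome, shock, cerebral infarction, pulmonary embolism and
peritonitis prefixes plus ICU/ventilation and death — deliberately
excluding reoperation and readmission, which indicate re-intervention
severity rather than a life threat. The shipped prefix lists are
*representative*, not a validated clinical code set; they are fully
overridable via CSV, and all quantitative results in this repository use
synthetic events generated from the same definitions, so conclusions are
definition-stable by construction.

## Statistical models

**2×2 odds ratios.** OR = (a/b)/(c/d) with the Wald CI
exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)). A zero cell raises an error with
guidance rather than applying a silent continuity correction. The same
quantity emerges from a saturated two-group logistic fit; the test suite
checks agreement to 1e-10.

**Logistic regression.** Fitting is by IRLS (statsmodels GLM, binomial
family; up to 50 iterations, tolerance 1e-10), wrapped to produce a
self-contained fit object (coefficients, covariance, log-likelihoods,
dummy-column grouping per variable). Treatment coding with declared
references: never-smoker, female, ASA I, CCI band 0. Age enters in years,
uncentered. Rows with any missing covariate are dropped first and counted.
Perfect separation is detected (via the fitter's own diagnostic and a
coefficient-magnitude guard) and raised as an error naming the covariate.
In small samples or specialty subsets, thin upper ASA/CCI bands are merged
downward (`collapse_sparse_levels`: a top band needs ≥50 rows and ≥5
events and non-events) before fitting — the standard guard against
quasi-complete separation of sparse ordinal levels; at full study scale
nothing merges.

**Variable importance.** (i) Partial Wald chi-squared per variable,
X = bᵀV_b⁻¹b over the variable's coefficient block (singular blocks fall
back to a pseudo-inverse with a warning), reported as percentage shares of
the total across modeled variables; shares are invariant to covariate
order. (ii) Shapley values on the linear-predictor (log-odds) scale. For
an additive predictor the Shapley value has the closed form
φ_j(i) = Σ_{k∈group j} β_k (x_ik − x̄_k), with dummy columns grouped per
variable and the in-sample covariate means as baseline; `exact_linear`
mode (the default, deterministic) computes this directly, and a seeded
Monte-Carlo permutation sampler estimates the same quantity for
cross-checking (≥10 permutations enforced). Efficiency —
Σ_j φ_j(i) = η_i − mean(η) — holds row-wise to 1e-9. Reported importance
is the mean absolute Shapley value per variable.

**Fit statistics.** McFadden R² = 1 − ℓ/ℓ₀;
Cox–Snell R² = 1 − exp(2(ℓ₀−ℓ)/n); Nagelkerke R² = Cox–Snell divided by
its maximum 1 − exp(2ℓ₀/n). No multiple-testing adjustment is applied
anywhere, matching the analysis style this package mirrors.

## Synthetic-data generator

The generator defines the study conditions under which everything is
tested; its defaults are fixed to the source cohort's printed marginals
and are not tuning knobs.

**Corpus.** ≥8 template families per class with slot fillers (cigarette
counts, packs, quit dates, pack-years) using the Finnish stems verbatim;
the hard boundary cases are modeled explicitly (dated quit → ex; "quit
recently"/pack-year history/e-cigarettes → unknown). Token-level noise
(default rate 0.05) applies one character substitution/deletion/
duplication per hit token, never touching the last intact stem token of a
non-unknown sentence, so the stem-filter invariant survives. Class mix
defaults to uniform quarters.

**Cohort.** One surgery per patient (a multi-surgery mode is a non-goal:
the mirrored analysis ignores clustering too). Status mix
(never, ex, current) = (0.5687, 0.1456, 0.2857). Per-status age is
truncated normal on [16, 100] with (μ, σ) = (56, 18) / (64, 14) / (53, 16);
male fractions 0.357 / 0.588 / 0.514; ASA distributions and the
prevalences of nine Charlson categories are status-conditional, ex-smokers
loaded heaviest. A lognormal patient frailty (σ = 1, mean 1) multiplies
comorbidity hazards to correlate categories and produce a realistic
multimorbidity tail (without it, counts ≥5 are vanishingly rare and the
top CCI band separates). The generator's band equals `compute_cci` applied
to the emitted ICD events — asserted in a test — so downstream modules see
consistent data.

Outcomes are drawn from logistic models on (status, age, sex, ASA, CCI
band). Conditional ORs vs never default to ex 1.09 / current 1.17
(overall) and 1.09 / 1.21 (critical). The non-status coefficients are the
generator's own choice, set so ASA dominates risk as in real surgical
data: per-year age 0.010/0.015 (overall/critical), male 0.10, ASA
(0, 0.35, 0.80, 1.30, 1.80) and (0, 0.60, 1.50, 2.50, 3.50), CCI bands up
to 1.10/1.30 on the log-odds scale. The intercept is calibrated by root
finding so the never-smoker marginal risk hits the configured baseline
(0.31 overall, 0.033 critical). The critical outcome is generated as a
subset of overall: critical is drawn from its model, and an additional
overall-only event with probability (p_ov − p_cr)/(1 − p_cr) keeps the
overall margin exact. Flagged surgeries materialize as ICD events
uniformly in days 0–90 (critical codes only for critical cases) or care
events; at most one death per patient and nothing after it; benign noise
diagnoses land outside the window to exercise filtering.

Status notes: 1–2 per patient (3% have none → unknown at assignment);
a configurable fraction (default 0.05 of the cohort, injected among ex-
and current smokers) carries genuinely conflicting note sequences that the
assignment rule resolves back to the true status — e.g. ex-smokers with an
old "current" note and a recent "never" note.

**What the generator does not emulate.** Real Finnish morphology and
orthography (templates are simplified, so the classifier's ~99% synthetic
accuracy far exceeds what heterogeneous clinical text allows — published
sentence-level precisions around 95–97% with recalls of 67–93% are the
realistic reference); status misclassification correlated with patient
risk; repeated surgeries per patient; pack-year dose; secular trends in
smoking prevalence; per-specialty effect heterogeneity (specialty is a
label with a configurable mix only). Passing tests therefore demonstrate
correctness of the machinery and recoverability of known parameters under
realistic confounding — not clinical performance on real records.

## Validation design

Three kinds of evidence back the implementation: (1) exact reproduction of
published crude ORs, CIs and rates from printed counts; (2) independent
oracles — direct likelihood maximization for IRLS, permutation enumeration
for Shapley, exhaustive 3-D grid enumeration for threshold tuning, a
brute-force checker for the Charlson mapping, and exhaustive enumeration
of the assignment rule; (3) simulation: across 100 seeds of 20 000-surgery
cohorts the adjusted model's 95% CIs cover the configured conditional ORs
at the nominal rate while the crude ex-smoker OR is confounded upward,
and across corpus seeds the tuned policy holds its precision floor on
held-out sentences. Problem sizes in the test suite (cohorts of 2 500–
100 000, corpora of 1 500–10 000) are chosen so the full suite and the
acceptance script each run in a few minutes on one core.

## Known limitations

The outcome code lists are representative rather than clinically
validated; the published adjusted ORs and importance tables cannot be
reproduced without the original registry, so they are covered by
parameter-recovery targets instead; the Wald/normal approximation is used
for all CIs (adequate at these denominators, anti-conservative for very
rare cells); the classifier is linear and monolingual by design —
contextual models and other languages are out of scope.
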