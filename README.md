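# smokesurg

Smoking status from clinical free text, and smoking as a risk factor for
postoperative complications.

Large surgical registries rarely record smoking status in a structured
field; it hides in free-text notes ("lopettanut tupakoinnin 3/20", "stopped
smoking recently"). `smokesurg` reimplements, as a tested and reusable
pipeline, the full computational chain of a registry study of smoking and
90-day surgical complications:

1. **Sentence classification with abstention.** Sentences containing the
   word stems `tupak*` / `aski*` / `smok*` are normalized and classified
   into {current smoker, ex-smoker, never-smoker, unknown} by a linear
   bag-of-n-grams model (averaged hashed unigram+bigram embeddings into a
   softmax layer, trained by SGD). Per-class probability thresholds
   θ = (θ_current, θ_ex, θ_never), tuned on validation data, reroute
   low-confidence predictions to *unknown*: the argmax class c is kept only
   if P(c) ≥ θ_c. Thresholds are chosen to maximize total retained
   known-class recall subject to each class's precision ≥ 0.95
   (precision is favoured because a wrong status is worse than a missing
   one in the risk analysis).
2. **Surgery-level status assignment.** A patient's classified,
   timestamped observations collapse to one preoperative status per
   surgery: the most recent observation on or before the surgery date
   wins, *unless* it says never-smoker while an earlier note documents
   smoking — then the status is ex-smoker.
3. **Covariates and outcomes.** The Charlson comorbidity index is computed
   from ICD-10 codes (Quan coding, shipped as an editable CSV, with the
   metastatic-tumour and severe-liver hierarchy rules). Two composite
   outcomes are flagged per surgery over an inclusive day-0–90 window:
   *overall* (wound, cardiovascular, neurological, respiratory,
   thromboembolic, gastroenterological, urinary, orthopaedic and
   unspecified-infection codes, plus death, reoperation, readmission and
   ICU/ventilation) and *critical* (acute coronary syndrome, shock,
   cerebral infarction, pulmonary embolism, peritonitis, ICU/ventilation,
   death) — a strict subset.
4. **Risk estimation.** Crude odds ratios from 2×2 tables with Wald CIs,
   `exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))`; adjusted ORs from
   maximum-likelihood logistic regression (IRLS) of outcome on smoking
   status + age + sex + ASA class + CCI band (treatment coding, references
   never / female / ASA I / band 0). Relative variable importance by the
   partial Wald chi-squared X = bᵀV_b⁻¹b of each coefficient block (as %
   shares) and by mean |Shapley value| on the log-odds scale
   (φ_j(i) = Σ_{k∈j} β_k(x_ik − x̄_k) for the additive predictor), plus
   McFadden and Nagelkerke pseudo-R².
5. **Synthetic registry.** Because the original hospital data cannot be
   shared, a first-class generator emulates it: Finnish-style template
   sentences with the hard boundary cases, and a cohort whose
   age/sex/ASA/comorbidity distributions are status-conditional so that
   crude ORs are confounded upward (ex-smokers oldest and sickest) while
   the outcome model's *conditional* ORs are known — making parameter
   recovery testable end to end.

## Worked example

Crude odds ratios recomputed from the published per-status counts
(`python examples/01_published_odds_ratios.py`):

```
overall  ex       OR 1.82 (95% CI 1.77 to 1.87)
overall  current  OR 1.50 (95% CI 1.47 to 1.54)
critical ex       OR 2.15 (95% CI 2.02 to 2.29)
critical current  OR 1.62 (95% CI 1.53 to 1.71)
```

The same machinery on a synthetic 8 000-surgery registry, end to end
(`python examples/05_full_study_pipeline.py`), shows what adjustment does:

```
group  outcome smoking_status      model  odds_ratio  ci_low  ci_high
  all  overall        current unadjusted        1.51    1.35     1.68
  all  overall             ex unadjusted        1.74    1.52     1.99
  all  overall        current   adjusted        1.31    1.18     1.47
  all  overall             ex   adjusted        1.13    0.98     1.31
```

The crude ex-smoker OR of 1.74 collapses to 1.13 after adjustment — the
cohort was generated with a conditional ex-smoker OR of 1.09, and the
excess was confounding by age, ASA class and comorbidity. In the
importance table ASA class carries most of the explainable risk
(Wald share ≈ 68%), with smoking comparable to age.

Other examples: `02_synthetic_registry.py` (confounding structure),
`03_train_abstaining_classifier.py` (tuned precision ≥ 0.95 on held-out
sentences), `04_status_rule_and_scoring.py` (assignment rule, Charlson
hierarchy, outcome window). A thin CLI wraps the pipeline:
`smokesurg run --seed 1 --out runs/demo` and `smokesurg simulate`.

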