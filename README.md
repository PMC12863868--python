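# igwohealth

Grey-wolf-optimized random forests for pediatric health-risk stratification,
with Shapley-value interpretation.

Periodic physical examinations and questionnaires make childhood health
assessment slow and subjective; tabular screening data (physiological,
environmental and behavioral features) supports predictive modelling
instead, but random-forest classifiers are sensitive to their
hyperparameters and opaque to clinicians. This package addresses both
problems for a binary healthy-vs-subhealthy outcome:

* **Tuning.** An improved grey-wolf optimizer (IGWO) searches the forest's
  hyperparameter box — trees n ∈ [50, 200], depth d ∈ [5, 15], per-split
  feature fraction p ∈ (0.3, 0.8] — in a normalized unit cube. The three
  fittest wolves (α, β, δ) steer every position update
  (D_k = |C_k·X_k − x|, X_k′ = X_k − A_k·D_k, A = 2a·r₁ − a, C = 2·r₂),
  with three enhancements: a linear weight schedule a = 2 − 2t/T, elite
  opposition-based learning (X_new = X_best + F·(X_worst − X_best) for the
  top 10%), and elite retention (top 20% survive each generation). The
  objective is F(θ) = Σₖ₌₁⁵ Accuracy_k − λ·Complexity(θ): the sum of
  stratified 5-fold CV accuracies minus λ = 0.01 times a normalized
  tree-count/depth penalty. PSO (ω = 0.7) and random search provide
  baselines; a binary mode does feature selection.
* **Interpretation.** Shapley values φᵢ over the interventional coalition
  value f(S) (background-set expectation): exact subset enumeration as the
  oracle (d ≤ 15), permutation sampling for the 24-feature cohort, the
  Shapley interaction index for pairwise synergies, and mean-|φ| feature
  ranking.
* **Data.** The study's three-hospital cohort is private, so a synthetic
  generator reproduces its shape exactly — 1852 children, 1402/450 class
  split, subgroups 187/93/86/84, age 7.2 ± 2.3 on [3, 12], 3.2% missing
  cells — with planted signals (BMI strongest, then exercise time and PM2.5
  exposure). A preprocessing chain (chained-equations imputation,
  Tukey-fence winsorization capped at the 1st/99th percentiles, min-max
  scaling, one-hot encoding, stratified 70/30 split) completes the
  pipeline, and an experiments harness runs tuning, component ablations and
  model comparisons on shared splits.

See `docs/methods.md` for the full model description and design rationale.

## Worked example

```python
import numpy as np
from igwohealth import (CohortSpec, RFConfig, generate_cohort,
                        inject_missingness, preprocess_cohort, train_rf,
                        evaluate_on)

spec = CohortSpec(seed=1)                        # the study-shaped cohort
table = inject_missingness(generate_cohort(spec), spec.missing_rate,
                           np.random.default_rng(2))
X_tr, y_tr, X_te, y_te, names, report = preprocess_cohort(table, seed=42)
model = train_rf(RFConfig(150, 12, 0.33), X_tr, y_tr, seed=42)
print(report.split_sizes)
for k, v in evaluate_on(model, X_te, y_te).as_dict().items():
    print(f"{k:>10}: {v:.3f}")
```

prints

```
{'train': 1296, 'test': 556}
  accuracy: 0.975
 precision: 0.969
    recall: 0.926
        f1: 0.947
   auc_roc: 0.993
     kappa: 0.930
```

The 1296/556 sizes are the exact 70/30 stratified split of 1402 + 450;
accuracy far above the 0.757 majority-class floor (with κ = 0.93, which is
chance-corrected) shows the classifier recovers the cohort's planted
signal. Attributing the model's vote score with Shapley values
(`examples/04_explain_with_shapley.py`) ranks the features:

```
            feature  mean_abs_shap
rank
1               bmi       0.175688
2     exercise_time       0.045411
3     pm25_exposure       0.021940
```

i.e. BMI moves the forest's vote share by ~0.18 on average — the strongest
health determinant, with exercise time and PM2.5 exposure next, matching
the generator's planted ordering.

The `examples/` directory has one short script per capability (simulate,
preprocess, tune, explain, ablate/compare); a thin CLI mirrors them:
`igwohealth simulate|preprocess|tune|ablate|compare|explain --help`.

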