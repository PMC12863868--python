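"""Tune forest hyperparameters with the improved grey-wolf optimizer.

Wolves move in the normalized unit cube over three dimensions — number of
trees [50, 200], maximum depth [5, 15], per-split feature fraction
(0.3, 0.8] — maximizing the sum of 5-fold cross-validation accuracies minus
a small complexity penalty.  This example uses a small cohort and desk-scale
budgets so it finishes in about half a minute; the study-scale defaults are
30 wolves and 100 iterations.
"""

from igwohealth import CohortSpec
from igwohealth.experiments import ExperimentConfig, run_tuning

spec = CohortSpec(
    n=400,
    class_counts=(300, 100),
    subgroup_counts={"obesity": 42, "lipid": 20, "respiratory": 19, "hypertension": 19},
    sex_counts=(200, 200),
)
cfg = ExperimentConfig(
    cohort_spec=spec, population_size=6, max_iterations=5, seed=7, fast=True
)
result = run_tuning(cfg)

best = result.details["best_configs"][0]
print(
    f"best config: {best['n_trees']} trees, depth {best['max_depth']}, "
    f"feature fraction {best['p_features']:.2f}"
)
print(f"best fitness (sum of 5 fold accuracies - penalty): "
      f"{result.details['best_fitness'][0]:.4f}")
print(result.table.filter(["model", "accuracy_mean", "f1_mean", "auc_roc_mean"]).to_string(index=False))
# Fitness near 5.0 means near-perfect fold accuracies; the test-set row
# reports generalization of the final forest refit at the alpha wolf's
# configuration.
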