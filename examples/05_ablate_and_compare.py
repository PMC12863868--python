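"""Ablate the optimizer's enhancements and compare against baselines.

The ablation reruns tuning with each enhancement (dynamic weight, elite
opposition-based learning, elite retention) disabled in turn, on the
identical cohort and split.  The comparison pits the grey-wolf-tuned forest
against a PSO-tuned forest (inertia 0.7) and a fixed-configuration forest
(100 trees, depth 10, sqrt features).
"""

from igwohealth import CohortSpec
from igwohealth.experiments import ExperimentConfig, run_ablation, run_comparison

spec = CohortSpec(
    n=400,
    class_counts=(300, 100),
    subgroup_counts={"obesity": 42, "lipid": 20, "respiratory": 19, "hypertension": 19},
    sex_counts=(200, 200),
)
cfg = ExperimentConfig(
    cohort_spec=spec, population_size=4, max_iterations=2, seed=5, fast=True
)

print("=== ablation (one row per variant) ===")
print(run_ablation(cfg).table.filter(["model", "accuracy_mean", "f1_mean"]).to_string(index=False))

print("\n=== comparison (tuners vs fixed baseline) ===")
print(run_comparison(cfg).table.filter(["model", "accuracy_mean", "f1_mean"]).to_string(index=False))
# On this small, strongly-signaled synthetic cohort all variants score
# similarly; the harness exists to make the component contributions
# measurable, and differences grow with harder tuning landscapes.
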