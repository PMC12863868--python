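"""End-to-end experiment harness: tune, ablate, compare.

Each run follows the same protocol: simulate (or load) a cohort, inject
missingness, run the preprocessing chain with train-fitted transforms, tune
the random-forest hyperparameters on the training split via the
cross-validated fitness, fit the final forest at the optimum, and report the
full metric suite on the held-out test split.

Ablations rerun the tuner with one enhancement disabled at a time on the
*identical* cohort and split, with aligned seed streams, so differences are
attributable to the disabled component.  The comparison harness pits the
improved grey-wolf tuner against PSO tuning and a fixed-configuration forest
(100 trees, depth 10, sqrt features), with optional logistic-regression and
SVM baselines, and reports paired t statistics with Bonferroni adjustment
across repetition seeds.

Paper-scale budgets (30 wolves, 100 iterations) are the defaults; ``fast=True``
switches to desk-scale budgets suitable for iteration and CI.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortSpec, generate_cohort, inject_missingness, read_cohort_csv
from .fitness import FitnessConfig, MetricSet, cv_fitness, evaluate_on, train_rf
from .igwo import OptimizerConfig, optimize, optimize_pso
from .preprocessing import preprocess_cohort
from .search_space import CandidateVector, RFConfig, default_space, repair

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "ABLATION_VARIANTS",
    "run_tuning",
    "run_ablation",
    "run_comparison",
    "paired_ttest",
]

logger = logging.getLogger(__name__)

ABLATION_VARIANTS = (
    "full",
    "no_dynamic_weight",
    "no_elite_opposition",
    "no_elite_retention",
)

_VARIANT_FLAGS = {
    "full": {},
    "no_dynamic_weight": {"dynamic_weight": False},
    "no_elite_opposition": {"elite_opposition": False},
    "no_elite_retention": {"elite_retention": False},
}

#: fixed-configuration forest baseline in the comparison protocol
FIXED_RF_BASELINE = RFConfig(n_trees=100, max_depth=10, p_features=0.2, min_samples_leaf=1)


@dataclass(frozen=True)
class ExperimentConfig:
    """Resolved settings of one experiment; embedded in every result file."""

    cohort_spec: CohortSpec = field(default_factory=CohortSpec)
    cohort_csv: str | None = None
    population_size: int = 30
    max_iterations: int = 100
    repetitions: int = 1
    variants: tuple[str, ...] = ABLATION_VARIANTS
    train_fraction: float = 0.7
    fitness: FitnessConfig = field(default_factory=FitnessConfig)
    seed: int = 0
    fast: bool = False
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        unknown = set(self.variants) - set(ABLATION_VARIANTS)
        if unknown:
            raise ValueError(f"unknown ablation variants: {sorted(unknown)}")

    def budgets(self) -> tuple[int, int]:
        """(population, iterations) honoring the fast flag."""
        if self.fast:
            return min(self.population_size, 6), min(self.max_iterations, 6)
        return self.population_size, self.max_iterations


@dataclass
class ExperimentResult:
    """Tabular results plus the resolved config and all seeds used."""

    table: pd.DataFrame
    config: ExperimentConfig
    seeds: list[int]
    details: dict = field(default_factory=dict)

    def save(self, out_dir: str | Path, stem: str) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / f"{stem}.csv", index=False)
        payload = {
            "config": _config_dict(self.config),
            "seeds": self.seeds,
            "details": self.details,
        }
        (out / f"{stem}.json").write_text(json.dumps(payload, indent=2, default=str))


def _config_dict(cfg: ExperimentConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


# --------------------------------------------------------------------------
# shared plumbing
# --------------------------------------------------------------------------


def _prepare_data(cfg: ExperimentConfig, seed: int):
    """Simulate or load, inject missingness, preprocess. Seed-deterministic."""
    if cfg.cohort_csv is not None:
        table = read_cohort_csv(cfg.cohort_csv)
    else:
        spec = dataclasses.replace(cfg.cohort_spec, seed=seed)
        table = generate_cohort(spec)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 911]))
        table = inject_missingness(table, spec.missing_rate, rng)
    return preprocess_cohort(table, cfg.train_fraction, seed=cfg.fitness.seed)


def _fitness_fn(X, y, fc: FitnessConfig, space):
    def fn(candidate: CandidateVector) -> float:
        config = _decode(space, candidate)
        return cv_fitness(config, X, y, fc, space)

    return fn


def _decode(space, candidate: CandidateVector) -> RFConfig:
    from .search_space import decode

    return decode(space, repair(candidate))


def _tune_once(
    X_train,
    y_train,
    cfg: ExperimentConfig,
    seed: int,
    flags: dict,
    algorithm: str = "igwo",
):
    space = default_space()
    N, T = cfg.budgets()
    opt_cfg = OptimizerConfig(
        population_size=N, max_iterations=T, seed=seed, **flags
    )
    fn = _fitness_fn(X_train, y_train, cfg.fitness, space)
    if algorithm == "igwo":
        return optimize(fn, space, opt_cfg)
    if algorithm == "pso":
        return optimize_pso(fn, space, opt_cfg)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _metrics_row(name: str, metrics: list[MetricSet]) -> dict:
    row: dict = {"model": name}
    keys = metrics[0].as_dict().keys()
    for k in keys:
        vals = np.array([m.as_dict()[k] for m in metrics])
        row[f"{k}_mean"] = float(vals.mean())
        row[f"{k}_sd"] = float(vals.std(ddof=0)) if len(vals) > 1 else 0.0
    return row


# --------------------------------------------------------------------------
# drivers
# --------------------------------------------------------------------------


def run_tuning(cfg: ExperimentConfig) -> ExperimentResult:
    """Full workflow: simulate/load -> preprocess -> tune -> final fit -> test."""
    seeds = [cfg.seed + r for r in range(cfg.repetitions)]
    metrics, best_cfgs, fitnesses = [], [], []
    for seed in seeds:
        try:
            X_tr, y_tr, X_te, y_te, names, report = _prepare_data(cfg, seed)
        except Exception as exc:
            raise RuntimeError(f"data preparation failed (seed {seed})") from exc
        best, fit, trace = _tune_once(X_tr, y_tr, cfg, seed, flags={})
        model = train_rf(best, X_tr, y_tr, seed=cfg.fitness.seed)
        metrics.append(evaluate_on(model, X_te, y_te))
        best_cfgs.append(best)
        fitnesses.append(fit)
        logger.info("seed %d: best %s fitness %.4f", seed, best, fit)
    table = pd.DataFrame([_metrics_row("igwo_rf", metrics)])
    result = ExperimentResult(
        table=table,
        config=cfg,
        seeds=seeds,
        details={
            "best_configs": [dataclasses.asdict(b) for b in best_cfgs],
            "best_fitness": fitnesses,
        },
    )
    if cfg.out_dir:
        result.save(cfg.out_dir, "tuning")
    return result


def run_ablation(cfg: ExperimentConfig) -> ExperimentResult:
    """One tuning run per enhancement variant on shared data and splits."""
    if len(cfg.variants) < 2:
        raise ValueError("an ablation needs at least 2 variants")
    seeds = [cfg.seed + r for r in range(cfg.repetitions)]
    per_variant: dict[str, list[MetricSet]] = {v: [] for v in cfg.variants}
    per_variant_fitness: dict[str, list[float]] = {v: [] for v in cfg.variants}
    for seed in seeds:
        X_tr, y_tr, X_te, y_te, names, report = _prepare_data(cfg, seed)
        for variant in cfg.variants:
            best, fit, trace = _tune_once(
                X_tr, y_tr, cfg, seed, flags=_VARIANT_FLAGS[variant]
            )
            model = train_rf(best, X_tr, y_tr, seed=cfg.fitness.seed)
            per_variant[variant].append(evaluate_on(model, X_te, y_te))
            per_variant_fitness[variant].append(fit)
    rows = [_metrics_row(v, per_variant[v]) for v in cfg.variants]
    table = pd.DataFrame(rows)

    if "full" in cfg.variants:
        full_mean = np.mean(per_variant_fitness["full"])
        for v in cfg.variants:
            if v != "full" and np.mean(per_variant_fitness[v]) > full_mean:
                logger.warning(
                    "ablation soft check: variant %s mean fitness exceeds the "
                    "full model (%.4f > %.4f)",
                    v,
                    np.mean(per_variant_fitness[v]),
                    full_mean,
                )
    result = ExperimentResult(
        table=table,
        config=cfg,
        seeds=seeds,
        details={"mean_fitness": {v: float(np.mean(f)) for v, f in per_variant_fitness.items()}},
    )
    if cfg.out_dir:
        result.save(cfg.out_dir, "ablation")
    return result


def run_comparison(
    cfg: ExperimentConfig, include_linear_baselines: bool = False
) -> ExperimentResult:
    """IGWO-tuned vs PSO-tuned vs fixed-configuration forest on shared splits."""
    seeds = [cfg.seed + r for r in range(cfg.repetitions)]
    models: dict[str, list[MetricSet]] = {
        "igwo_rf": [],
        "pso_rf": [],
        "fixed_rf": [],
    }
    if include_linear_baselines:
        models["logistic"] = []
        models["svm"] = []

    for seed in seeds:
        X_tr, y_tr, X_te, y_te, names, report = _prepare_data(cfg, seed)
        n_feats = X_tr.shape[1]
        fixed = dataclasses.replace(
            FIXED_RF_BASELINE, p_features=max(1, int(np.sqrt(n_feats))) / n_feats
        )

        best_i, _, _ = _tune_once(X_tr, y_tr, cfg, seed, flags={}, algorithm="igwo")
        best_p, _, _ = _tune_once(X_tr, y_tr, cfg, seed, flags={}, algorithm="pso")
        for name, rf_cfg in (("igwo_rf", best_i), ("pso_rf", best_p), ("fixed_rf", fixed)):
            model = train_rf(rf_cfg, X_tr, y_tr, seed=cfg.fitness.seed)
            models[name].append(evaluate_on(model, X_te, y_te))

        if include_linear_baselines:
            from sklearn.linear_model import LogisticRegression
            from sklearn.svm import SVC

            from .fitness import auc_roc, cohen_kappa, compute_metrics, confusion_counts

            for name, est in (
                ("logistic", LogisticRegression(C=0.1, penalty="l2", solver="liblinear")),
                ("svm", SVC(C=1.0, kernel="rbf", gamma="scale", probability=False)),
            ):
                est.fit(X_tr, y_tr)
                pred = est.predict(X_te)
                scores = (
                    est.decision_function(X_te)
                    if hasattr(est, "decision_function")
                    else pred
                )
                counts = confusion_counts(y_te, pred)
                base = compute_metrics(counts)
                models[name].append(
                    MetricSet(
                        accuracy=base["accuracy"],
                        precision=base["precision"],
                        recall=base["recall"],
                        f1=base["f1"],
                        auc_roc=auc_roc(y_te, scores),
                        kappa=cohen_kappa(counts),
                    )
                )

    rows = [_metrics_row(name, ms) for name, ms in models.items()]
    table = pd.DataFrame(rows)

    details: dict = {}
    if cfg.repetitions >= 2:
        acc = {m: [x.accuracy for x in ms] for m, ms in models.items()}
        comparisons = [(m, "igwo_rf") for m in models if m != "igwo_rf"]
        tests = {}
        for other, ref in comparisons:
            t, p_adj = paired_ttest(acc[ref], acc[other], len(comparisons))
            tests[f"igwo_rf_vs_{other}"] = {"t": t, "p_bonferroni": p_adj}
        details["paired_tests_accuracy"] = tests
        if acc["igwo_rf"] and np.mean(acc["igwo_rf"]) < np.mean(acc["fixed_rf"]):
            logger.warning(
                "comparison soft check: tuned forest mean accuracy below the "
                "fixed baseline"
            )

    result = ExperimentResult(table=table, config=cfg, seeds=seeds, details=details)
    if cfg.out_dir:
        result.save(cfg.out_dir, "comparison")
    return result


def paired_ttest(a: list[float], b: list[float], n_comparisons: int = 1):
    """Paired t statistic and Bonferroni-adjusted p-value for two series."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if np.allclose(a, b):
        return 0.0, 1.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(min(1.0, p * n_comparisons))
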