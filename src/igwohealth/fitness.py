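"""Cross-validated, complexity-penalized fitness and evaluation metrics.

The tuning objective is

    F(theta) = sum_{k=1}^{K} Accuracy_k  -  lambda * Complexity(theta)

a *sum* (not a mean) of the K stratified cross-validation fold accuracies,
minus a penalty on ensemble size and tree depth:

    Complexity(theta) = n_trees / max(n_trees) + max_depth / max(max_depth)

which is bounded in (0, 2] over the default search space and monotone in both
arguments, discouraging oversized ensembles and deep trees.

The classifier scored by the fitness is a bagged decision-tree ensemble with
per-split feature subsampling, predicting by majority vote; the class-1 score
of a sample is the fraction of trees voting for class 1.  The ensemble is
built on scikit-learn's random forest, whose bootstrap/subsample/vote
semantics match this contract; the vote-fraction score is computed from the
individual trees rather than from averaged leaf probabilities.

Evaluation metrics (accuracy, precision, recall, F1, rank-based AUC-ROC,
Cohen's kappa) treat class 1 — the subhealthy/diseased minority — as the
positive class, so precision and recall describe risk detection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .search_space import HyperparameterSpace, RFConfig, default_space

__all__ = [
    "FitnessConfig",
    "MetricSet",
    "VoteForest",
    "complexity_penalty",
    "train_rf",
    "cv_fitness",
    "confusion_counts",
    "compute_metrics",
    "cohen_kappa",
    "auc_roc",
    "evaluate_on",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitnessConfig:
    """Settings of the tuning objective.

    ``alpha_reg`` is a second regularization coefficient recorded in the
    protocol but attached to no term; it is stored for completeness and is
    inert.
    """

    folds: int = 5
    lam: float = 0.01
    alpha_reg: float = 0.001
    seed: int = 42
    #: divide the fold-accuracy term by K (mean mode) instead of summing;
    #: off by default — the printed objective sums
    mean_mode: bool = False

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("cross-validation needs K >= 2 folds")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")


@dataclass(frozen=True)
class MetricSet:
    """The evaluation metrics reported for a classifier on one test set."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc_roc: float
    kappa: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc_roc": self.auc_roc,
            "kappa": self.kappa,
        }


# --------------------------------------------------------------------------
# classifier contract
# --------------------------------------------------------------------------


class VoteForest:
    """Random forest with explicit majority-vote semantics.

    Wraps a fitted scikit-learn forest; ``score1`` returns, per sample, the
    fraction of trees voting class 1, and ``predict`` is the majority vote
    (ties go to class 1, the risk class).
    """

    def __init__(self, forest: RandomForestClassifier):
        self._forest = forest

    @property
    def n_trees(self) -> int:
        return len(self._forest.estimators_)

    def score1(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        votes = np.zeros(X.shape[0])
        for tree in self._forest.estimators_:
            votes += tree.predict(X) == 1
        return votes / self.n_trees

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.score1(X) >= 0.5).astype(int)


def train_rf(config: RFConfig, X: np.ndarray, y: np.ndarray, seed: int) -> VoteForest:
    """Fit the bagged tree ensemble at the given hyperparameters.

    Bootstrap resamples per tree, ``p_features`` of the columns considered at
    each split, depth capped at ``max_depth``, leaves of at least
    ``min_samples_leaf`` samples.  Deterministic under a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.isnan(X).any():
        raise ValueError("training matrix contains missing values; impute first")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class; cannot fit a classifier")
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        max_features=config.p_features,
        min_samples_leaf=config.min_samples_leaf,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return VoteForest(forest)


# --------------------------------------------------------------------------
# fitness
# --------------------------------------------------------------------------


def complexity_penalty(config: RFConfig, space: HyperparameterSpace | None = None) -> float:
    """Normalized model-size penalty ``n_trees/max + depth/max``, in (0, 2]."""
    space = space or default_space()
    uppers = {d.name: d.upper for d in space.dims}
    return config.n_trees / uppers["n_trees"] + config.max_depth / uppers["max_depth"]


def cv_fitness(
    config: RFConfig,
    X: np.ndarray,
    y: np.ndarray,
    fc: FitnessConfig | None = None,
    space: HyperparameterSpace | None = None,
) -> float:
    """Sum of stratified K-fold accuracies minus the complexity penalty."""
    fc = fc or FitnessConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y)
    if (counts[counts > 0] < fc.folds).any():
        raise ValueError(
            f"stratification impossible: a class has fewer members than K={fc.folds}"
        )
    skf = StratifiedKFold(n_splits=fc.folds, shuffle=True, random_state=fc.seed)
    accs = []
    for train_idx, test_idx in skf.split(X, y):
        model = train_rf(config, X[train_idx], y[train_idx], seed=fc.seed)
        pred = model.predict(X[test_idx])
        accs.append(float(np.mean(pred == y[test_idx])))
    logger.debug("per-fold accuracies: %s", accs)
    total = sum(accs) / fc.folds if fc.mean_mode else sum(accs)
    return total - fc.lam * complexity_penalty(config, space)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------


def confusion_counts(y_true, y_pred) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) with class 1 (subhealthy/diseased) as positive."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return tp, tn, fp, fn


def compute_metrics(counts: tuple[int, int, int, int]) -> dict[str, float]:
    """Accuracy, precision, recall and F1 from confusion counts.

    An undefined precision or recall (zero denominator) is reported as 0
    with a warning, and F1 follows suit.
    """
    tp, tn, fp, fn = counts
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion counts")
    accuracy = (tp + tn) / total
    if tp + fp == 0:
        warnings.warn("precision undefined (no positive predictions); reporting 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("recall undefined (no positive truths); reporting 0")
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return {"accuracy": accuracy, "precision": precision, "recall": recall, "f1": f1}


def cohen_kappa(counts: tuple[int, int, int, int]) -> float:
    """Chance-corrected agreement ``(p_o - p_e) / (1 - p_e)``.

    ``p_o`` is observed agreement; ``p_e`` the agreement expected from the
    row/column marginals.  The degenerate ``p_e = 1`` case returns 1 for
    perfect agreement and 0 otherwise, with a warning.
    """
    tp, tn, fp, fn = counts
    n = tp + tn + fp + fn
    if n == 0:
        raise ValueError("empty confusion counts")
    p_o = (tp + tn) / n
    p_yes = ((tp + fp) / n) * ((tp + fn) / n)
    p_no = ((tn + fn) / n) * ((tn + fp) / n)
    p_e = p_yes + p_no
    if p_e == 1.0:
        warnings.warn("kappa degenerate (expected agreement = 1)")
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def auc_roc(y_true, scores) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) estimator.

    Midranks handle ties, making the value identical to the trapezoidal area
    under the empirical ROC curve; invariant under strictly monotone score
    transforms.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)  # midranks
    rank_sum_pos = ranks[y_true == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def evaluate_on(model: VoteForest, X: np.ndarray, y: np.ndarray) -> MetricSet:
    """Full metric suite for a fitted classifier on a labelled test set."""
    pred = model.predict(X)
    counts = confusion_counts(y, pred)
    base = compute_metrics(counts)
    return MetricSet(
        accuracy=base["accuracy"],
        precision=base["precision"],
        recall=base["recall"],
        f1=base["f1"],
        auc_roc=auc_roc(y, model.score1(X)),
        kappa=cohen_kappa(counts),
    )
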