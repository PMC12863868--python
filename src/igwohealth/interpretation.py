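"""Shapley-value attribution for tabular classifiers.

The contribution of feature ``i`` to a model's score at sample ``x`` is the
Shapley value

    phi_i = sum_{S subset F\\{i}}  |S|! (|F|-|S|-1)! / |F|!  [f(S u {i}) - f(S)]

where the coalition value ``f(S)`` is the *interventional* expectation: the
mean model score over a background set with the features in ``S`` taken from
``x`` and the rest from the background row.  Exact enumeration is feasible up
to ~15 features and serves as the oracle; a permutation-sampling estimator
(unbiased, Monte-Carlo error shrinking as 1/sqrt(m)) covers wider frames.
Pairwise synergies use the Shapley interaction index, the weighted second
difference over coalitions excluding the pair.

Efficiency — base value plus all contributions reconstructing the score —
holds exactly in exact mode and is the module's principal internal check.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd

__all__ = [
    "AttributionResult",
    "shapley_exact",
    "shapley_sampled",
    "shapley_interaction",
    "rank_importance",
    "attribute_samples",
]

_EXACT_LIMIT = 15
_INTERACTION_LIMIT = 12


@dataclass
class AttributionResult:
    """Per-sample, per-feature Shapley values with the shared base value."""

    values: np.ndarray  # (n_samples, n_features)
    base_value: float  # f(empty coalition)
    scores: np.ndarray  # model score per attributed sample
    feature_names: tuple[str, ...] | None = None

    @property
    def importance(self) -> np.ndarray:
        """Mean absolute contribution per feature across samples."""
        return np.abs(self.values).mean(axis=0)

    def efficiency_gap(self) -> np.ndarray:
        """Per-sample |phi_0 + sum_i phi_i - score|; ~0 in exact mode."""
        return np.abs(self.base_value + self.values.sum(axis=1) - self.scores)


# --------------------------------------------------------------------------
# coalition value function
# --------------------------------------------------------------------------


class _CoalitionValue:
    """Caches f(S) = E_b[ score(x_S, b_{F\\S}) ] over the background set."""

    def __init__(self, model_score, x: np.ndarray, background: np.ndarray):
        self.score = model_score
        self.x = np.asarray(x, dtype=float)
        self.bg = np.asarray(background, dtype=float)
        if self.bg.ndim != 2 or len(self.bg) == 0:
            raise ValueError("background must be a nonempty 2-D sample set")
        self._cache: dict[frozenset, float] = {}

    def __call__(self, subset) -> float:
        key = frozenset(subset)
        if key not in self._cache:
            hybrid = self.bg.copy()
            idx = sorted(key)
            hybrid[:, idx] = self.x[idx]
            self._cache[key] = float(np.mean(self.score(hybrid)))
        return self._cache[key]

    def evaluate_many(self, subsets: list[tuple]) -> np.ndarray:
        """Evaluate several coalitions with one stacked model call."""
        todo = [s for s in subsets if frozenset(s) not in self._cache]
        if todo:
            m = len(self.bg)
            stack = np.tile(self.bg, (len(todo), 1))
            for j, s in enumerate(todo):
                idx = sorted(s)
                stack[j * m : (j + 1) * m, idx] = self.x[idx]
            scores = np.asarray(self.score(stack), dtype=float)
            for j, s in enumerate(todo):
                self._cache[frozenset(s)] = float(scores[j * m : (j + 1) * m].mean())
        return np.array([self._cache[frozenset(s)] for s in subsets])


# --------------------------------------------------------------------------
# estimators
# --------------------------------------------------------------------------


def shapley_exact(
    model_score,
    x: np.ndarray,
    background: np.ndarray,
    feature_names: tuple[str, ...] | None = None,
) -> AttributionResult:
    """Exact Shapley values by full subset enumeration (one sample).

    Enumerates all ``2^d`` coalitions; refused above 15 features — use
    :func:`shapley_sampled` there.
    """
    x = np.asarray(x, dtype=float).ravel()
    d = x.shape[0]
    if d > _EXACT_LIMIT:
        raise ValueError(
            f"{d} features exceeds the exact-enumeration limit ({_EXACT_LIMIT}); "
            "use shapley_sampled"
        )
    v = _CoalitionValue(model_score, x, background)
    all_subsets = [
        s for size in range(d + 1) for s in combinations(range(d), size)
    ]
    v.evaluate_many(all_subsets)

    phi = np.zeros(d)
    fact = [factorial(k) for k in range(d + 1)]
    for i in range(d):
        others = [j for j in range(d) if j != i]
        for size in range(d):
            w = fact[size] * fact[d - size - 1] / fact[d]
            for s in combinations(others, size):
                phi[i] += w * (v(s + (i,)) - v(s))

    base = v(())
    score = v(tuple(range(d)))
    return AttributionResult(
        values=phi[None, :],
        base_value=base,
        scores=np.array([score]),
        feature_names=feature_names,
    )


def shapley_sampled(
    model_score,
    x: np.ndarray,
    background: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
    feature_names: tuple[str, ...] | None = None,
) -> AttributionResult:
    """Permutation-sampling Shapley estimate (one sample).

    Averages the marginal contribution of each feature over random orderings;
    unbiased for the exact values, with the full d+1 coalition chain of each
    permutation evaluated in one batched model call.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    x = np.asarray(x, dtype=float).ravel()
    d = x.shape[0]
    v = _CoalitionValue(model_score, x, background)
    phi = np.zeros(d)
    for _ in range(n_permutations):
        order = rng.permutation(d)
        prefixes = [tuple(sorted(order[:k])) for k in range(d + 1)]
        vals = v.evaluate_many(prefixes)
        for k, feat in enumerate(order):
            phi[feat] += vals[k + 1] - vals[k]
    phi /= n_permutations
    return AttributionResult(
        values=phi[None, :],
        base_value=v(()),
        scores=np.array([v(tuple(range(d)))]),
        feature_names=feature_names,
    )


def shapley_interaction(
    model_score,
    x: np.ndarray,
    background: np.ndarray,
    pair: tuple[int, int],
) -> float:
    """Shapley interaction index for a feature pair.

    Weighted sum over coalitions ``S`` excluding both features of the second
    difference ``f(S+ij) - f(S+i) - f(S+j) + f(S)``; symmetric in the pair,
    zero for additive models.
    """
    i, j = pair
    if i == j:
        raise ValueError("interaction requires two distinct features")
    x = np.asarray(x, dtype=float).ravel()
    d = x.shape[0]
    if d > _INTERACTION_LIMIT:
        raise ValueError(
            f"{d} features exceeds the exact interaction limit ({_INTERACTION_LIMIT})"
        )
    v = _CoalitionValue(model_score, x, background)
    others = [k for k in range(d) if k not in (i, j)]
    fact = [factorial(k) for k in range(d + 1)]
    total = 0.0
    for size in range(len(others) + 1):
        w = fact[size] * fact[d - size - 2] / fact[d - 1]
        for s in combinations(others, size):
            total += w * (
                v(s + (i, j)) - v(s + (i,)) - v(s + (j,)) + v(s)
            )
    return total


# --------------------------------------------------------------------------
# cohort-level helpers
# --------------------------------------------------------------------------


def attribute_samples(
    model_score,
    X: np.ndarray,
    background: np.ndarray,
    mode: str = "sampled",
    n_permutations: int = 2000,
    rng: np.random.Generator | None = None,
    feature_names: tuple[str, ...] | None = None,
) -> AttributionResult:
    """Attribute every row of ``X``; sampled mode is the wide-frame default."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    rows = []
    base = None
    scores = []
    for xi in X:
        if mode == "exact":
            res = shapley_exact(model_score, xi, background, feature_names)
        elif mode == "sampled":
            if rng is None:
                raise ValueError("sampled mode requires an rng")
            res = shapley_sampled(
                model_score, xi, background, n_permutations, rng, feature_names
            )
        else:
            raise ValueError(f"unknown attribution mode {mode!r}")
        rows.append(res.values[0])
        base = res.base_value
        scores.append(res.scores[0])
    return AttributionResult(
        values=np.vstack(rows),
        base_value=float(base),
        scores=np.array(scores),
        feature_names=feature_names,
    )


def rank_importance(result: AttributionResult) -> pd.DataFrame:
    """Features sorted by mean |contribution|, ties broken by name."""
    imp = result.importance
    names = result.feature_names or tuple(f"f{i}" for i in range(len(imp)))
    frame = pd.DataFrame({"feature": names, "mean_abs_shap": imp})
    frame = frame.sort_values(
        ["mean_abs_shap", "feature"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    frame.index = frame.index + 1
    frame.index.name = "rank"
    return frame
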