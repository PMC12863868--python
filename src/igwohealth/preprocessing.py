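"""Preprocessing chain: imputation, winsorization, scaling, encoding, split.

The chain mirrors a standard clinical-tabular pipeline:

1. chained-equations imputation (5 cycles) fills missing entries;
2. Tukey-fence outlier detection with winsorization caps extremes at the
   1st/99th percentiles;
3. min-max scaling maps continuous columns to [0, 1];
4. one-hot encoding expands categorical columns;
5. a stratified 70/30 split preserves the class mix.

Outlier handling and imputation operate on the full table (imputation first,
so fences are computed on completed columns); scaling and encoding parameters
are fit on the training split only and applied unchanged to the test split,
guarding against leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CATEGORICAL_LEVELS, CohortTable

__all__ = [
    "PreprocessReport",
    "mice_impute",
    "tukey_winsorize",
    "min_max_scale",
    "one_hot_encode",
    "stratified_split",
    "preprocess_cohort",
]


@dataclass
class PreprocessReport:
    """Audit trail of what each stage did to each column."""

    n_imputed: dict[str, int] = field(default_factory=dict)
    n_winsorized: dict[str, int] = field(default_factory=dict)
    caps: dict[str, tuple[float, float]] = field(default_factory=dict)
    scale_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    split_sizes: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_imputed": self.n_imputed,
            "n_winsorized": self.n_winsorized,
            "caps": {k: list(v) for k, v in self.caps.items()},
            "scale_params": {k: list(v) for k, v in self.scale_params.items()},
            "split_sizes": self.split_sizes,
        }


# --------------------------------------------------------------------------
# chained-equations imputation
# --------------------------------------------------------------------------


def _design_matrix(frame: pd.DataFrame, exclude: str) -> np.ndarray:
    """Numeric predictor matrix from all columns except ``exclude``.

    Categorical predictors are one-hot encoded (full set of levels).
    """
    cols = []
    for col in frame.columns:
        if col == exclude:
            continue
        if col in CATEGORICAL_LEVELS or frame[col].dtype == object:
            levels = sorted(pd.unique(frame[col].dropna().astype(str)))
            for lv in levels:
                cols.append((frame[col].astype(str) == lv).astype(float).values)
        else:
            cols.append(frame[col].astype(float).values)
    X = np.column_stack(cols) if cols else np.empty((len(frame), 0))
    return np.column_stack([np.ones(len(frame)), X])


def mice_impute(
    table: CohortTable, cycles: int = 5, rng: np.random.Generator | None = None
) -> CohortTable:
    """Multivariate imputation by chained equations.

    Missing entries start at the column mean (mode for categorical columns);
    each cycle then sweeps the incomplete columns in frame order, regresses
    the column on all others — ordinary least squares for continuous
    columns, nearest-class-centroid assignment for categorical ones — and
    replaces its missing entries with the predictions.  Observed entries are
    never altered.  Deterministic: the conditional models involve no random
    draws, so ``rng`` is accepted for interface symmetry only.
    """
    frame = table.features.copy()
    mask = table.missing_mask

    all_missing = [c for c in frame.columns if frame[c].isna().all()]
    if all_missing:
        raise ValueError(
            "cannot impute columns that are entirely missing: " + ", ".join(all_missing)
        )
    if not mask.values.any():
        return table.copy()

    # initialization: column mean / mode
    for col in frame.columns:
        miss = mask[col].values
        if not miss.any():
            continue
        if col in CATEGORICAL_LEVELS or frame[col].dtype == object:
            mode = frame[col].dropna().mode().iloc[0]
            frame.loc[miss, col] = mode
        else:
            frame.loc[miss, col] = frame[col].astype(float).mean()

    incomplete = [c for c in frame.columns if mask[c].values.any()]
    for _ in range(cycles):
        for col in incomplete:
            miss = mask[col].values
            X = _design_matrix(frame, exclude=col)
            if col in CATEGORICAL_LEVELS or frame[col].dtype == object:
                # nearest class centroid on the predictors
                obs_vals = frame.loc[~miss, col].astype(str)
                levels = sorted(obs_vals.unique())
                centroids = np.array(
                    [X[~miss][(obs_vals == lv).values].mean(axis=0) for lv in levels]
                )
                d2 = ((X[miss, None, :] - centroids[None, :, :]) ** 2).sum(-1)
                frame.loc[miss, col] = np.array(levels)[np.argmin(d2, axis=1)]
            else:
                y = frame[col].astype(float).values
                beta, *_ = np.linalg.lstsq(X[~miss], y[~miss], rcond=None)
                frame.loc[miss, col] = X[miss] @ beta

    out = table.copy()
    out.features = frame
    return out


# --------------------------------------------------------------------------
# column transforms
# --------------------------------------------------------------------------


def tukey_winsorize(column: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Cap Tukey-fence outliers at the 1st/99th percentiles.

    Fences are ``Q1 - 1.5 IQR`` and ``Q3 + 1.5 IQR``; a value beyond the
    lower/upper fence is replaced by the column's 1st/99th percentile
    (linear-interpolation estimator).  Returns the modified column and the
    ``(p1, p99)`` cap pair.
    """
    x = np.asarray(column, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 4:
        raise ValueError("winsorization needs at least 4 finite values")
    q1, q3 = np.percentile(x[finite], [25, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    p1, p99 = np.percentile(x[finite], [1, 99])
    out = x.copy()
    out[finite & (x < lo_fence)] = p1
    out[finite & (x > hi_fence)] = p99
    return out, (float(p1), float(p99))


def min_max_scale(
    column: np.ndarray, params: tuple[float, float] | None = None
) -> tuple[np.ndarray, tuple[float, float]]:
    """Affine map to [0, 1]; pass ``params`` to reuse a fitted (min, max).

    A constant column maps to all zeros with a warning.  At transform time,
    values outside the fitted range map outside [0, 1] (no clipping), so the
    inverse transform stays exact.
    """
    x = np.asarray(column, dtype=float)
    if params is None:
        lo, hi = float(np.nanmin(x)), float(np.nanmax(x))
    else:
        lo, hi = params
    if hi == lo:
        warnings.warn("constant column: min-max scaling maps it to 0")
        return np.zeros_like(x), (lo, hi)
    return (x - lo) / (hi - lo), (lo, hi)


def one_hot_encode(
    column, levels: tuple[str, ...] | None = None
) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Indicator matrix with one column per category, lexicographic order.

    No level is dropped, so every row sums to 1.  Pass the fitted ``levels``
    at transform time; an unseen category raises with its name.
    """
    col = pd.Series(column).astype(str)
    if levels is None:
        levels = tuple(sorted(col.unique()))
    unseen = set(col.unique()) - set(levels)
    if unseen:
        raise ValueError(f"unseen categories at encode time: {sorted(unseen)}")
    mat = pd.DataFrame({lv: (col == lv).astype(float).values for lv in levels})
    return mat, levels


def stratified_split(
    table: CohortTable, train_fraction: float = 0.7, seed: int = 42
) -> tuple[CohortTable, CohortTable]:
    """Class-preserving train/test partition.

    Per-class training counts are set by largest-remainder apportionment of
    ``round(train_fraction * n)`` seats; rows are shuffled within class under
    the seed.  The two parts form an exact partition of the input rows.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    y = table.label.values
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present to stratify")
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 members to split")

    n = len(y)
    total_train = int(round(train_fraction * n))
    quotas = train_fraction * counts
    base = np.floor(quotas).astype(int)
    remainder = total_train - base.sum()
    order = np.argsort(-(quotas - base), kind="stable")
    take = base.copy()
    for i in range(int(remainder)):
        take[order[i % len(classes)]] += 1

    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls, k in zip(classes, take):
        rows = np.flatnonzero(y == cls)
        rows = rng.permutation(rows)
        train_idx.extend(rows[:k].tolist())
        test_idx.extend(rows[k:].tolist())
    train_idx, test_idx = sorted(train_idx), sorted(test_idx)
    if not test_idx or not train_idx:
        raise ValueError("degenerate split: one side is empty")

    def subset(idx: list[int]) -> CohortTable:
        return CohortTable(
            features=table.features.iloc[idx].reset_index(drop=True),
            label=table.label.iloc[idx].reset_index(drop=True),
            subgroup=table.subgroup.iloc[idx].reset_index(drop=True),
            missing_mask=table.missing_mask.iloc[idx].reset_index(drop=True),
            metadata=None
            if table.metadata is None
            else table.metadata.iloc[idx].reset_index(drop=True),
        )

    return subset(train_idx), subset(test_idx)


# --------------------------------------------------------------------------
# full chain
# --------------------------------------------------------------------------


def preprocess_cohort(
    table: CohortTable,
    train_fraction: float = 0.7,
    seed: int = 42,
    cycles: int = 5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str], PreprocessReport]:
    """Impute, winsorize, split, then scale/encode fit on train only.

    Returns ``(X_train, y_train, X_test, y_test, feature_names, report)``
    with fully numeric matrices and no missing entries.  Deterministic under
    a fixed seed.
    """
    report = PreprocessReport()
    report.n_imputed = {
        c: int(table.missing_mask[c].sum()) for c in table.features.columns
    }
    completed = mice_impute(table, cycles=cycles)

    numeric_cols = [
        c
        for c in completed.features.columns
        if c not in CATEGORICAL_LEVELS and completed.features[c].dtype != object
    ]
    for col in numeric_cols:
        before = completed.features[col].astype(float).values
        after, caps = tukey_winsorize(before)
        report.n_winsorized[col] = int(np.sum(after != before))
        report.caps[col] = caps
        completed.features[col] = after

    train, test = stratified_split(completed, train_fraction, seed)
    report.split_sizes = {"train": train.n, "test": test.n}

    blocks_train, blocks_test, names = [], [], []
    for col in completed.features.columns:
        if col in numeric_cols:
            tr, params = min_max_scale(train.features[col].values)
            te, _ = min_max_scale(test.features[col].values, params=params)
            report.scale_params[col] = params
            blocks_train.append(tr[:, None])
            blocks_test.append(te[:, None])
            names.append(col)
        else:
            fixed = (
                tuple(sorted(CATEGORICAL_LEVELS[col]))
                if col in CATEGORICAL_LEVELS
                else None
            )
            tr_mat, levels = one_hot_encode(train.features[col].values, levels=fixed)
            te_mat, _ = one_hot_encode(test.features[col].values, levels=levels)
            blocks_train.append(tr_mat.values)
            blocks_test.append(te_mat.values)
            names.extend(f"{col}={lv}" for lv in levels)

    X_train = np.hstack(blocks_train)
    X_test = np.hstack(blocks_test)
    return (
        X_train,
        train.label.values.astype(int),
        X_test,
        test.label.values.astype(int),
        names,
        report,
    )
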