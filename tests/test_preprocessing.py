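"""Imputation, winsorization, scaling, encoding and stratified splitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igwohealth.cohort import CohortSpec, CohortTable, generate_cohort
from igwohealth.preprocessing import (
    mice_impute,
    min_max_scale,
    one_hot_encode,
    preprocess_cohort,
    stratified_split,
    tukey_winsorize,
)


def _table_from_frame(frame, label=None):
    n = len(frame)
    return CohortTable(
        features=frame,
        label=pd.Series(label if label is not None else np.zeros(n, int)),
        subgroup=pd.Series([""] * n),
        missing_mask=frame.isna(),
    )


class TestMiceImpute:
    def test_identity_without_missing(self):
        frame = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = mice_impute(_table_from_frame(frame))
        pd.testing.assert_frame_equal(out.features, frame)

    def test_constant_column_filled_with_constant(self):
        frame = pd.DataFrame(
            {"a": [7.0, 7.0, np.nan, 7.0, 7.0], "b": [1.0, 2.0, 3.0, 4.0, 5.0]}
        )
        out = mice_impute(_table_from_frame(frame))
        assert out.features["a"].iloc[2] == pytest.approx(7.0)

    def test_observed_entries_never_altered(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        holes = frame.copy()
        holes.iloc[::7, 1] = np.nan
        table = _table_from_frame(holes)
        out = mice_impute(table)
        observed = ~table.missing_mask
        assert np.allclose(
            out.features.values[observed.values], holes.values[observed.values]
        )
        assert not out.features.isna().values.any()

    def test_beats_mean_imputation_on_correlated_data(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 2000
            z = rng.multivariate_normal([0, 0], [[1, 0.9], [0.9, 1]], size=n)
            frame = pd.DataFrame({"a": z[:, 0], "b": z[:, 1]})
            miss = rng.choice(n, int(0.2 * n), replace=False)
            truth = frame["b"].values.copy()
            holes = frame.copy()
            holes.loc[miss, "b"] = np.nan
            out = mice_impute(_table_from_frame(holes))
            rmse = np.sqrt(np.mean((out.features["b"].values[miss] - truth[miss]) ** 2))
            mean_rmse = np.sqrt(
                np.mean((np.nanmean(holes["b"]) - truth[miss]) ** 2)
            )
            wins += rmse < mean_rmse
        assert wins >= 19

    def test_all_missing_column_refused(self):
        frame = pd.DataFrame({"a": [np.nan, np.nan], "b": [1.0, 2.0]})
        with pytest.raises(ValueError, match="a"):
            mice_impute(_table_from_frame(frame))

    def test_categorical_imputation_uses_levels(self):
        rng = np.random.default_rng(1)
        n = 200
        x = rng.normal(size=n)
        cat = np.where(x > 0, "yes", "no").astype(object)
        cat[::11] = None
        frame = pd.DataFrame({"dietary_habits": cat, "x": x})
        out = mice_impute(_table_from_frame(frame))
        filled = out.features["dietary_habits"]
        assert set(filled.unique()) <= {"yes", "no"}
        # nearest-centroid assignment should respect the x <> category link
        imputed_rows = frame["dietary_habits"].isna()
        agree = (filled[imputed_rows] == np.where(x[imputed_rows] > 0, "yes", "no")).mean()
        assert agree > 0.8


class TestTukeyWinsorize:
    def test_no_outliers_unchanged(self):
        x = np.arange(10, dtype=float)
        out, _ = tukey_winsorize(x)
        assert np.array_equal(out, x)

    def test_printed_outlier_capped_at_p99(self):
        x = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 1000.0])
        out, caps = tukey_winsorize(x)
        # upper fence Q3 + 1.5 IQR is exceeded only by 1000, which is set to
        # the column's 99th percentile (linear interpolation)
        assert out[-1] == pytest.approx(np.percentile(x, 99))
        assert caps[1] == pytest.approx(np.percentile(x, 99))
        assert np.array_equal(out[:-1], x[:-1])

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_idempotent_with_sparse_outliers(self, seed):
        # regime where outliers are < 1% of the column, so the 99th
        # percentile lies inside the fences and re-application is a no-op
        rng = np.random.default_rng(seed)
        x = rng.normal(size=500)
        k = int(rng.integers(0, 3))
        if k:
            idx = rng.choice(500, k, replace=False)
            x[idx] += rng.choice([-1, 1], k) * rng.uniform(6, 12, k)
        once, _ = tukey_winsorize(x)
        twice, _ = tukey_winsorize(once)
        assert np.allclose(once, twice)

    def test_rank_order_preserved_among_unmodified(self, rng):
        x = rng.normal(size=300)
        x[:3] += 15
        out, _ = tukey_winsorize(x)
        untouched = out == x
        assert (np.argsort(x[untouched], kind="stable") == np.argsort(out[untouched], kind="stable")).all()

    def test_too_few_values_refused(self):
        with pytest.raises(ValueError):
            tukey_winsorize(np.array([1.0, 2.0, 3.0]))


class TestMinMaxScale:
    def test_basic_mapping(self):
        out, params = min_max_scale(np.array([0.0, 5.0, 10.0]))
        assert np.allclose(out, [0.0, 0.5, 1.0])
        assert params == (0.0, 10.0)

    def test_constant_column_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="constant"):
            out, _ = min_max_scale(np.array([7.0, 7.0, 7.0]))
        assert np.allclose(out, 0.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_round_trip_inverse(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(scale=10, size=50)
        scaled, (lo, hi) = min_max_scale(x)
        assert np.allclose(scaled * (hi - lo) + lo, x, atol=1e-12)


class TestOneHotEncode:
    def test_indicator_layout(self):
        mat, levels = one_hot_encode(["b", "a", "c", "b"])
        assert levels == ("a", "b", "c")
        assert np.array_equal(mat.loc[0].values, [0, 1, 0])
        assert (mat.sum(axis=1) == 1).all()

    def test_single_level_column(self):
        mat, levels = one_hot_encode(["x", "x"])
        assert levels == ("x",)
        assert (mat.values == 1).all()

    def test_unseen_category_named_in_error(self):
        with pytest.raises(ValueError, match="zebra"):
            one_hot_encode(["a", "zebra"], levels=("a", "b"))

    @given(st.lists(st.sampled_from("abcd"), min_size=1, max_size=40))
    @settings(max_examples=30, deadline=None)
    def test_rows_sum_to_one(self, values):
        mat, _ = one_hot_encode(values)
        assert (mat.sum(axis=1) == 1).all()


class TestStratifiedSplit:
    def test_study_cohort_split_sizes(self):
        table = generate_cohort(CohortSpec(seed=1))
        train, test = stratified_split(table, 0.7, seed=42)
        assert (train.n, test.n) == (1296, 556)
        assert int((train.label == 0).sum()) == 981
        assert int((train.label == 1).sum()) == 315

    def test_partition_property(self, small_cohort):
        train, test = stratified_split(small_cohort, 0.7, seed=0)
        assert train.n + test.n == small_cohort.n
        # class proportions preserved to < 1 row
        for cls in (0, 1):
            frac_full = (small_cohort.label == cls).mean()
            expected_train = frac_full * train.n
            assert abs(int((train.label == cls).sum()) - expected_train) < 1.0

    def test_degenerate_fraction_refused(self, small_cohort):
        with pytest.raises(ValueError):
            stratified_split(small_cohort, 1.0, seed=0)

    def test_single_class_refused(self):
        frame = pd.DataFrame({"a": np.arange(10, dtype=float)})
        table = _table_from_frame(frame, label=np.zeros(10, int))
        with pytest.raises(ValueError, match="both classes"):
            stratified_split(table, 0.7, seed=0)


class TestFullChain:
    def test_deterministic_and_complete(self, small_cohort):
        r1 = preprocess_cohort(small_cohort, seed=42)
        r2 = preprocess_cohort(small_cohort, seed=42)
        X1, y1, Xt1, yt1, names1, _ = r1
        X2, y2, Xt2, yt2, names2, _ = r2
        assert np.array_equal(X1, X2) and np.array_equal(Xt1, Xt2)
        assert np.array_equal(y1, y2)
        assert names1 == names2
        assert not np.isnan(X1).any() and not np.isnan(Xt1).any()

    def test_train_scaling_bounds_and_report(self, small_preprocessed):
        X_tr, y_tr, X_te, y_te, names, report = small_preprocessed
        # scaled training columns live in [0, 1]; test may spill slightly
        assert X_tr.min() >= 0.0 and X_tr.max() <= 1.0
        assert report.split_sizes == {"train": 280, "test": 120}
        assert sum(report.n_imputed.values()) == round(0.032 * 400 * 24)
        # one-hot expansion: 22 numeric + 3 dietary + 2 smoking levels
        assert len(names) == 27
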