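"""Blocked CV: fold geometry, leakage guard, metrics, scoring, comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from refcast import (
    CVPlan,
    HistoricalAverageForecaster,
    MonthlySeries,
    RandomWalkForecaster,
    compare_models,
    cross_validate,
    make_blocked_folds,
    median_absolute_error,
    median_absolute_percentage_error,
    wrap_external_forecaster,
)
from refcast.base import adapter_from_estimator
from refcast.errors import (
    InsufficientDataError,
    InvalidArgumentError,
    UndefinedMetricError,
)
from refcast.evaluation import ScoreTable
from refcast.series import Forecast


class TestFolds:
    def test_default_layout_on_89_months(self):
        plan = CVPlan(seed=0)
        folds = make_blocked_folds(89, plan, repetition_seed=5)
        assert len(folds) == 5
        for train, test in folds:
            assert max(train) < min(test)
            assert len(train) == 15 and len(test) == 12

    def test_test_blocks_disjoint(self):
        plan = CVPlan()
        folds = make_blocked_folds(100, plan, repetition_seed=11)
        covered = sorted(i for _, test in folds for i in test)
        assert len(covered) == len(set(covered))

    def test_deterministic_under_seed(self):
        plan = CVPlan()
        a = make_blocked_folds(89, plan, 3)
        b = make_blocked_folds(89, plan, 3)
        assert a == b

    def test_exact_minimum_unique_layout(self):
        """At the minimum feasible length the layout is forced, seed-independent."""
        plan = CVPlan(n_folds=3, train_window_months=5, horizons=(2,))
        min_len = plan.minimum_series_length()
        assert min_len == 5 + 3 * 2
        layouts = {tuple((t.start, t.stop, s.start, s.stop)
                         for t, s in make_blocked_folds(min_len, plan, seed))
                   for seed in range(10)}
        assert len(layouts) == 1

    def test_infeasible_geometry_reports_minimum(self):
        plan = CVPlan()
        with pytest.raises(InsufficientDataError, match=str(plan.minimum_series_length())):
            make_blocked_folds(30, plan, 0)


class TestMetrics:
    def test_mae_hand_computed(self):
        assert median_absolute_error([10, 12], [11, 15]) == 2.0

    def test_mae_perfect_prediction(self):
        assert median_absolute_error([1, 2, 3], [1, 2, 3]) == 0.0

    def test_mae_robust_to_one_outlier(self):
        actual = np.arange(10.0)
        pred = actual.copy()
        pred[0] += 1000
        assert median_absolute_error(actual, pred) == 0.0

    def test_mape_hand_computed(self):
        assert median_absolute_percentage_error([10, 20], [11, 15]) == pytest.approx(17.5)

    def test_mape_zero_actual_skipped(self):
        assert median_absolute_percentage_error([0, 10], [5, 10]) == 0.0

    def test_mape_all_zero_undefined(self):
        with pytest.raises(UndefinedMetricError):
            median_absolute_percentage_error([0, 0], [1, 2])

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            median_absolute_error([1, 2], [1])

    @settings(derandomize=True, max_examples=30)
    @given(
        st.lists(st.floats(min_value=1, max_value=100), min_size=2, max_size=20),
        st.floats(min_value=1.0, max_value=5.0),
    )
    def test_inflating_errors_never_decreases_metrics(self, actual, factor):
        """Scaling every prediction error by a factor > 1 is monotone."""
        actual = np.asarray(actual)
        rng = np.random.default_rng(1)
        err = rng.normal(0, 1, actual.size)
        base_pred = actual + err
        worse_pred = actual + factor * err
        assert (median_absolute_error(actual, worse_pred)
                >= median_absolute_error(actual, base_pred) - 1e-12)
        assert (median_absolute_percentage_error(actual, worse_pred)
                >= median_absolute_percentage_error(actual, base_pred) - 1e-12)


def _baseline_adapters():
    return [
        adapter_from_estimator("random_walk", RandomWalkForecaster()),
        adapter_from_estimator("historical_average", HistoricalAverageForecaster()),
    ]


class TestCrossValidate:
    def test_oracle_model_scores_zero(self, referral_series):
        """A model returning the true future gets MAE 0 and MAPE 0 everywhere."""
        counts = referral_series.counts.astype(float)

        def oracle(series, horizon, seed):
            start = series.months[-1].ordinal - referral_series.months[0].ordinal + 1
            truth = counts[start : start + horizon]
            return Forecast(horizon=horizon, point=truth, lower=truth,
                            upper=truth, level=0.95)

        plan = CVPlan(n_repetitions=3, seed=2)
        table = cross_validate(referral_series,
                               [wrap_external_forecaster("oracle", oracle)], plan)
        assert (table.scores["mae"] == 0).all()
        assert (table.scores["mape_percent"] == 0).all()

    def test_deterministic_under_seed(self, referral_series):
        plan = CVPlan(n_repetitions=4, seed=9)
        t1 = cross_validate(referral_series, _baseline_adapters(), plan)
        t2 = cross_validate(referral_series, _baseline_adapters(), plan)
        pd.testing.assert_frame_equal(t1.scores, t2.scores)

    def test_model_order_invariant(self, referral_series):
        plan = CVPlan(n_repetitions=3, seed=4)
        fwd = cross_validate(referral_series, _baseline_adapters(), plan)
        rev = cross_validate(referral_series, _baseline_adapters()[::-1], plan)
        merged = fwd.scores.merge(rev.scores, on=["model", "horizon_months"])
        np.testing.assert_allclose(merged["mae_x"], merged["mae_y"])

    def test_no_temporal_leakage(self, referral_series):
        """No training index may reach any test index, 100 seeded repetitions."""
        plan = CVPlan(n_repetitions=1, seed=0)
        for rep_seed in range(100):
            for train, test in make_blocked_folds(len(referral_series), plan, rep_seed):
                assert max(train) < min(test)

    def test_repetition_seeds_nested(self):
        """The first 100 repetitions of a 1000-repetition run use the same folds."""
        plan_small = CVPlan(n_repetitions=100, seed=21)
        plan_large = CVPlan(n_repetitions=1000, seed=21)
        seeds_small = np.random.SeedSequence(plan_small.seed).generate_state(100)
        seeds_large = np.random.SeedSequence(plan_large.seed).generate_state(1000)
        np.testing.assert_array_equal(seeds_small, seeds_large[:100])


class TestCompareModels:
    def _table(self, fold_errors):
        rows = []
        for (model, h, metric), arr in fold_errors.items():
            if metric != "mae":
                continue
            rows.append({"model": model, "horizon_months": h,
                         "mae": float(np.median(arr)),
                         "mape_percent": np.nan, "sd": float(np.std(arr))})
        return ScoreTable(scores=pd.DataFrame(rows), fold_errors=fold_errors)

    def test_identical_models_ratio_one(self):
        errs = np.abs(np.random.default_rng(0).normal(2, 0.5, 20))
        table = self._table({("a", 1, "mae"): errs, ("b", 1, "mae"): errs.copy()})
        report = compare_models(table, ["b"])
        row = report.iloc[0]
        assert row["mae_ratio"] == pytest.approx(1.0)
        assert row["p_permutation"] > 0.9

    def test_halved_errors_significant(self):
        base = np.abs(np.random.default_rng(1).normal(4, 0.5, 20))
        table = self._table({("model", 1, "mae"): base / 2,
                             ("baseline", 1, "mae"): base})
        report = compare_models(table, ["baseline"], seed=5)
        assert report.iloc[0]["p_permutation"] < 0.01

    def test_missing_baseline_rejected(self):
        table = self._table({("a", 1, "mae"): np.ones(5)})
        with pytest.raises(InvalidArgumentError):
            compare_models(table, ["nope"])

    def test_report_deterministic(self):
        rng = np.random.default_rng(3)
        table = self._table({("a", 1, "mae"): rng.random(15),
                             ("b", 1, "mae"): rng.random(15)})
        r1 = compare_models(table, ["b"], seed=11)
        r2 = compare_models(table, ["b"], seed=11)
        pd.testing.assert_frame_equal(r1, r2)
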