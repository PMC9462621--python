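"""Blocked cross-validation with median-error scoring.

Each repetition places ``n_folds`` non-overlapping test blocks of length
``max(horizons)`` at random (seeded) positions in the series, each block
immediately preceded by its own ``train_window_months`` training block, so
training data always strictly precedes test data within a fold.  Models are
refitted per fold on the training block only and scored on the first ``h``
test points for every requested horizon ``h``; the cell score is the median
over all fold-level medians across repetitions, with dispersion reported as
the standard deviation of fold-level medians.

Metrics follow the robust convention for volatile count data: the median
absolute error and the median absolute percentage error (0-100 scale),
with zero-actual percentage terms skipped and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .base import ForecasterAdapter
from .errors import (
    InsufficientDataError,
    InvalidArgumentError,
    RefcastError,
    UndefinedMetricError,
)
from .series import MonthlySeries

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVPlan:
    """Blocked cross-validation layout and replication settings."""

    n_folds: int = 5
    train_window_months: int = 15
    horizons: tuple = (1, 3, 6, 12)
    n_repetitions: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_folds < 1 or self.train_window_months < 1 or self.n_repetitions < 1:
            raise InvalidArgumentError("folds, train window and repetitions must be >= 1")
        if not self.horizons or any(h < 1 for h in self.horizons):
            raise InvalidArgumentError("horizons must be positive integers")

    @property
    def test_block_length(self) -> int:
        return max(self.horizons)

    def minimum_series_length(self) -> int:
        return self.train_window_months + self.n_folds * self.test_block_length


def make_blocked_folds(series_length: int, plan: CVPlan,
                       repetition_seed: int) -> list[tuple[range, range]]:
    """One repetition's folds: ``(train index range, test index range)`` pairs.

    Test blocks are disjoint and each is immediately preceded by its own
    training block; block placement is drawn uniformly at random (seeded)
    among feasible layouts.
    """
    L = plan.test_block_length
    w = plan.train_window_months
    k = plan.n_folds
    min_len = plan.minimum_series_length()
    if series_length < min_len:
        raise InsufficientDataError(
            f"series of length {series_length} cannot hold {k} folds "
            f"({w}-month training + {L}-month test blocks); minimum is {min_len}"
        )
    rng = np.random.default_rng(repetition_seed)
    # choose k disjoint test-block start positions in [w, series_length - L]
    # via the standard stars-and-bars gap construction: distribute the slack
    # uniformly among the k+1 gaps around the blocks.
    slack = series_length - min_len
    if slack == 0:
        starts = [w + i * L for i in range(k)]
    else:
        cuts = np.sort(rng.integers(0, slack + 1, size=k))
        starts = [w + int(cuts[i]) + i * L for i in range(k)]
    folds = []
    for s in starts:
        train = range(s - w, s)
        test = range(s, s + L)
        folds.append((train, test))
    return folds


def median_absolute_error(actual, predicted) -> float:
    """Median of |actual - predicted|."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.size != predicted.size:
        raise InvalidArgumentError("actual and predicted must have equal length")
    if actual.size == 0:
        raise InvalidArgumentError("empty input")
    return float(np.median(np.abs(actual - predicted)))


def median_absolute_percentage_error(actual, predicted) -> float:
    """Median of 100 |actual - predicted| / actual over non-zero actuals."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.size != predicted.size:
        raise InvalidArgumentError("actual and predicted must have equal length")
    nonzero = actual != 0
    skipped = int(np.sum(~nonzero))
    if skipped:
        logger.warning("MAPE: skipped %d zero-actual term(s)", skipped)
    if not nonzero.any():
        raise UndefinedMetricError("MAPE undefined: all actual values are zero")
    terms = 100.0 * np.abs(actual[nonzero] - predicted[nonzero]) / actual[nonzero]
    return float(np.median(terms))


@dataclass
class ScoreTable:
    """Cross-validation scores per (model, horizon) with fold-level detail."""

    scores: pd.DataFrame  # columns: model, horizon_months, mae, mape_percent, sd
    fold_errors: dict = field(default_factory=dict)
    # fold_errors[(model, horizon, metric)] -> 1-D array of fold-level medians
    n_failures: dict = field(default_factory=dict)

    def cell(self, model: str, horizon: int) -> pd.Series:
        df = self.scores
        row = df[(df["model"] == model) & (df["horizon_months"] == horizon)]
        if row.empty:
            raise InvalidArgumentError(f"no scores for model {model!r} horizon {horizon}")
        return row.iloc[0]

    def to_csv(self, path) -> None:
        self.scores.to_csv(path, index=False)


def cross_validate(series: MonthlySeries, models: list[ForecasterAdapter],
                   plan: CVPlan) -> ScoreTable:
    """Blocked cross-validation of every model under the plan.

    All randomness (fold placement per repetition, any model stochasticity)
    derives from ``plan.seed``.  A model failure on a fold is logged and
    excluded from that model's scores, never silently dropped.
    """
    if isinstance(series, MonthlySeries):
        n = len(series)
    else:
        series = MonthlySeries.from_start("2000-01", np.asarray(series))
        n = len(series)
    root = np.random.SeedSequence(plan.seed)
    rep_seeds = root.generate_state(plan.n_repetitions)
    metrics = {"mae": median_absolute_error, "mape": median_absolute_percentage_error}
    fold_errors: dict = {(m.name, h, met): [] for m in models for h in plan.horizons
                         for met in metrics}
    n_failures = {m.name: 0 for m in models}

    for rep in range(plan.n_repetitions):
        folds = make_blocked_folds(n, plan, int(rep_seeds[rep]) % (2**31))
        for fold_i, (train_idx, test_idx) in enumerate(folds):
            train = series.slice(train_idx.start, train_idx.stop)
            actual_full = series.counts[test_idx.start : test_idx.stop].astype(float)
            model_seed = int((rep_seeds[rep] + fold_i) % (2**31))
            for model in models:
                try:
                    forecast = model(train, plan.test_block_length, model_seed)
                except RefcastError as exc:
                    n_failures[model.name] += 1
                    logger.warning("model %s failed on repetition %d fold %d: %s",
                                   model.name, rep, fold_i, exc)
                    continue
                for h in plan.horizons:
                    a, pr = actual_full[:h], forecast.point[:h]
                    for met, fn in metrics.items():
                        try:
                            fold_errors[(model.name, h, met)].append(fn(a, pr))
                        except UndefinedMetricError:
                            logger.warning("%s undefined for model %s fold %d",
                                           met, model.name, fold_i)

    rows = []
    errors_out = {}
    for model in models:
        for h in plan.horizons:
            mae_arr = np.asarray(fold_errors[(model.name, h, "mae")])
            mape_arr = np.asarray(fold_errors[(model.name, h, "mape")])
            errors_out[(model.name, h, "mae")] = mae_arr
            errors_out[(model.name, h, "mape")] = mape_arr
            rows.append(
                {
                    "model": model.name,
                    "horizon_months": h,
                    "mae": float(np.median(mae_arr)) if mae_arr.size else np.nan,
                    "mape_percent": float(np.median(mape_arr)) if mape_arr.size else np.nan,
                    "sd": float(np.std(mae_arr, ddof=1)) if mae_arr.size > 1 else 0.0,
                }
            )
    table = pd.DataFrame(rows).sort_values(["model", "horizon_months"]).reset_index(drop=True)
    return ScoreTable(scores=table, fold_errors=errors_out, n_failures=n_failures)


def compare_models(table: ScoreTable, baseline_names: list[str],
                   n_permutations: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Error ratios and paired sign-flip permutation p-values vs each baseline.

    For every (model, baseline, horizon) the fold-level MAE medians are
    paired (truncated to the common length) and the observed mean difference
    is compared with its sign-flip permutation null.
    """
    models = sorted(table.scores["model"].unique())
    horizons = sorted(table.scores["horizon_months"].unique())
    for b in baseline_names:
        if b not in models:
            raise InvalidArgumentError(f"baseline {b!r} not present in score table")
    rng = np.random.default_rng(seed)
    rows = []
    for model in models:
        for baseline in baseline_names:
            if model == baseline:
                continue
            for h in horizons:
                e_m = table.fold_errors.get((model, h, "mae"), np.empty(0))
                e_b = table.fold_errors.get((baseline, h, "mae"), np.empty(0))
                k = min(len(e_m), len(e_b))
                if k == 0:
                    continue
                diff = np.asarray(e_m[:k]) - np.asarray(e_b[:k])
                obs = diff.mean()
                if np.allclose(diff, 0):
                    pval = 1.0
                else:
                    signs = rng.choice([-1.0, 1.0], size=(n_permutations, k))
                    null = (signs * diff).mean(axis=1)
                    pval = float((np.sum(np.abs(null) >= abs(obs)) + 1)
                                 / (n_permutations + 1))
                ratio = (table.cell(model, h)["mae"] / table.cell(baseline, h)["mae"]
                         if table.cell(baseline, h)["mae"] > 0 else np.inf)
                rows.append(
                    {
                        "model": model,
                        "baseline": baseline,
                        "horizon_months": h,
                        "mae_ratio": float(ratio),
                        "p_permutation": pval,
                    }
                )
    return pd.DataFrame(rows)
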