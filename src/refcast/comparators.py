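"""Baseline and comparator forecasters.

Two conventional baselines anchor the evaluation:

* random walk — every future point equals the last observed value, with
  interval width growing as sqrt(h) from the one-step difference SD;
* historical average — every future point equals the training mean.

The third comparator is an additive regression forecaster: piecewise-linear
growth with shrunken changepoints, yearly Fourier seasonality, and optional
custom indicator windows (e.g. a lockdown period), fitted by penalised least
squares.  It approximates the structure of additive decomposable regression
models popular for business time series; weekly seasonality is meaningless
at monthly resolution and is not modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .base import BaseForecaster
from .errors import FitFailureError, InvalidArgumentError, InvalidConfigError
from .series import Forecast, MonthlySeries

logger = logging.getLogger(__name__)


class RandomWalkForecaster(BaseForecaster):
    """Naive last-value forecast; interval half-width z * sigma * sqrt(h)."""

    def __init__(self, level: float = 0.95):
        self.level = level

    def _fit(self, series: MonthlySeries) -> None:
        y = series.values
        self.last_value_ = float(y[-1])
        if y.size < 2:
            logger.warning("single-observation series: interval width undefined, using 0")
            self.sigma_ = 0.0
        else:
            self.sigma_ = float(np.std(np.diff(y), ddof=1)) if y.size > 2 else float(
                np.abs(np.diff(y))[0]
            )

    def _predict(self, horizon: int) -> Forecast:
        point = np.full(horizon, self.last_value_)
        z = stats.norm.ppf(0.5 + self.level / 2.0)
        half = z * self.sigma_ * np.sqrt(np.arange(1, horizon + 1))
        return Forecast(horizon=horizon, point=point, lower=point - half,
                        upper=point + half, level=self.level)


class HistoricalAverageForecaster(BaseForecaster):
    """All-history mean forecast; constant interval half-width z*sigma*sqrt(1+1/n)."""

    def __init__(self, level: float = 0.95):
        self.level = level

    def _fit(self, series: MonthlySeries) -> None:
        y = series.values
        self.mean_ = float(y.mean())
        self.sigma_ = float(y.std(ddof=1)) if y.size > 1 else 0.0
        self.n_ = y.size

    def _predict(self, horizon: int) -> Forecast:
        point = np.full(horizon, self.mean_)
        z = stats.norm.ppf(0.5 + self.level / 2.0)
        half = np.full(horizon, z * self.sigma_ * np.sqrt(1.0 + 1.0 / self.n_))
        return Forecast(horizon=horizon, point=point, lower=point - half,
                        upper=point + half, level=self.level)


@dataclass(frozen=True)
class AdditiveModelConfig:
    """Configuration of the additive regression forecaster.

    ``custom_windows`` are closed ``('YYYY-MM', 'YYYY-MM')`` month pairs
    receiving their own level-shift coefficient (zero outside their span,
    also at forecast time).
    """

    n_changepoints: int = 10
    changepoint_penalty: float = 1.0
    fourier_order: int = 2
    custom_windows: tuple = ()
    level: float = 0.95

    def __post_init__(self):
        if self.n_changepoints < 0:
            raise InvalidConfigError("n_changepoints must be non-negative")
        if self.changepoint_penalty < 0:
            raise InvalidConfigError("changepoint_penalty must be non-negative")
        if self.fourier_order < 1:
            raise InvalidConfigError("fourier_order must be positive")
        if not 0 < self.level < 1:
            raise InvalidConfigError("level must lie in (0, 1)")


def _design(t: np.ndarray, config: AdditiveModelConfig,
            months: pd.PeriodIndex | None, changepoints: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(t), t]
    for cp in changepoints:
        cols.append(np.maximum(t - cp, 0.0))
    for k in range(1, config.fourier_order + 1):
        ang = 2.0 * np.pi * k * t / 12.0
        cols.append(np.cos(ang))
        cols.append(np.sin(ang))
    for (start, end) in config.custom_windows:
        if months is None:
            raise InvalidArgumentError("custom windows require a month-indexed series")
        lo, hi = pd.Period(start, freq="M"), pd.Period(end, freq="M")
        base = months[0]
        # forecast rows beyond the window are zero by construction
        cols.append(np.array([(base + int(ti) >= lo) and (base + int(ti) <= hi)
                              for ti in t], dtype=float))
    return np.column_stack(cols)


class AdditiveRegressionForecaster(BaseForecaster):
    """Piecewise-linear trend + yearly Fourier + indicator windows.

    Changepoint slope deltas get an L1-style penalty, approximated by
    iteratively reweighted ridge regression, so unused changepoints shrink
    to zero and the trend extrapolates from its final segment.
    """

    def __init__(self, n_changepoints: int = 10, changepoint_penalty: float = 1.0,
                 fourier_order: int = 2, custom_windows: tuple = (),
                 level: float = 0.95):
        self.n_changepoints = n_changepoints
        self.changepoint_penalty = changepoint_penalty
        self.fourier_order = fourier_order
        self.custom_windows = custom_windows
        self.level = level

    @property
    def _config(self) -> AdditiveModelConfig:
        return AdditiveModelConfig(
            n_changepoints=self.n_changepoints,
            changepoint_penalty=self.changepoint_penalty,
            fourier_order=self.fourier_order,
            custom_windows=tuple(self.custom_windows),
            level=self.level,
        )

    def _fit(self, series: MonthlySeries) -> None:
        config = self._config
        y = series.values
        n = y.size
        if n < 24:
            raise InvalidArgumentError(
                f"additive regression needs at least 24 months, got {n}"
            )
        t = np.arange(n, dtype=float)
        # candidate changepoints evenly spaced over the first 80% of the span,
        # strictly inside the training window
        if config.n_changepoints > 0:
            cps = np.linspace(0, 0.8 * (n - 1), config.n_changepoints + 2)[1:-1]
        else:
            cps = np.empty(0)
        X = _design(t, config, series.months, cps)
        n_cp = cps.size
        cp_slice = slice(2, 2 + n_cp)

        # IRLS approximation to L1 shrinkage on the changepoint deltas
        penalty = np.zeros(X.shape[1])
        beta = None
        for _ in range(20 if (config.changepoint_penalty > 0 and n_cp) else 1):
            A = X.T @ X + np.diag(penalty)
            try:
                beta_new = np.linalg.solve(A, X.T @ y)
            except np.linalg.LinAlgError as exc:
                raise FitFailureError(f"rank-deficient additive design: {exc}")
            if beta is not None and np.max(np.abs(beta_new - beta)) < 1e-10:
                beta = beta_new
                break
            beta = beta_new
            if config.changepoint_penalty > 0 and n_cp:
                deltas = np.abs(beta[cp_slice])
                penalty[cp_slice] = config.changepoint_penalty / np.maximum(deltas, 1e-8)
        cond = np.linalg.cond(X.T @ X + np.diag(penalty))
        if not np.isfinite(cond) or cond > 1e14:
            raise FitFailureError("additive design is numerically rank-deficient")

        self.coefficients_ = beta
        self.changepoints_ = cps
        resid = y - X @ beta
        dof = max(n - np.count_nonzero(np.abs(beta) > 1e-8), 1)
        self.sigma_ = float(np.sqrt(np.sum(resid**2) / dof))
        self.n_ = n

    def _predict(self, horizon: int) -> Forecast:
        config = self._config
        t_future = np.arange(self.n_, self.n_ + horizon, dtype=float)
        Xf = _design(t_future, config, self.series_.months, self.changepoints_)
        point = Xf @ self.coefficients_
        z = stats.norm.ppf(0.5 + self.level / 2.0)
        half = np.full(horizon, z * self.sigma_)
        return Forecast(horizon=horizon, point=point, lower=point - half,
                        upper=point + half, level=self.level)

    @property
    def slope_(self) -> float:
        """Final-segment trend slope (base slope plus all changepoint deltas)."""
        n_cp = self.changepoints_.size
        return float(self.coefficients_[1] + self.coefficients_[2 : 2 + n_cp].sum())


# ---------------------------------------------------------------------------
# thin functional wrappers


def random_walk_forecast(series: MonthlySeries, horizon: int,
                         level: float = 0.95) -> Forecast:
    return RandomWalkForecaster(level=level).fit(series).predict(horizon)


def historical_average_forecast(series: MonthlySeries, horizon: int,
                                level: float = 0.95) -> Forecast:
    return HistoricalAverageForecaster(level=level).fit(series).predict(horizon)


def additive_regression_forecast(series: MonthlySeries, horizon: int,
                                 config: AdditiveModelConfig | None = None) -> Forecast:
    config = config or AdditiveModelConfig()
    model = AdditiveRegressionForecaster(
        n_changepoints=config.n_changepoints,
        changepoint_penalty=config.changepoint_penalty,
        fourier_order=config.fourier_order,
        custom_windows=config.custom_windows,
        level=config.level,
    )
    return model.fit(series).predict(horizon)
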