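"""Seasonal-trend decomposition using loess (STL) and a stationarity check.

The decomposition is additive: ``y(t) = seasonal(t) + trend(t) + remainder(t)``
with the remainder defined by exact subtraction, so additivity is an identity.
The algorithm follows the classic scheme: an inner loop alternating
cycle-subseries loess smoothing of the detrended series (seasonal update,
followed by a low-pass filter to stop the seasonal absorbing low-frequency
variation) with loess smoothing of the deseasonalised series (trend update),
and an optional robust outer loop that downweights outlying remainders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InsufficientDataError, InvalidArgumentError
from .loess import LoessConfig, _fit_at, _bisquare
from .series import MonthlySeries


def default_seasonal_config() -> LoessConfig:
    """Seasonal smoother: window 13, locally constant (degree 0)."""
    return LoessConfig(window=13, degree=0)


def default_trend_config(period: int = 12, seasonal_window: int = 13) -> LoessConfig:
    """Trend smoother: smallest odd window >= 1.5 p / (1 - 1.5 / n_s), degree 1."""
    w = int(np.ceil(1.5 * period / (1.0 - 1.5 / seasonal_window)))
    if w % 2 == 0:
        w += 1
    return LoessConfig(window=w, degree=1)


def _lowpass_window(period: int) -> int:
    w = period if period % 2 == 1 else period + 1
    return w


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="valid")


@dataclass(frozen=True)
class DecompositionResult:
    """Additive seasonal / trend / remainder components of a monthly series."""

    seasonal: np.ndarray
    trend: np.ndarray
    remainder: np.ndarray
    period: int
    months: pd.PeriodIndex | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "seasonal": self.seasonal,
                "trend": self.trend,
                "remainder": self.remainder,
            }
        )
        if self.months is not None:
            df.insert(0, "month", self.months.astype(str))
        return df


def _smooth_weighted(x, y, config: LoessConfig, eval_points, weights) -> np.ndarray:
    """Loess with externally supplied robustness weights (outer-loop support)."""
    return np.array(
        [_fit_at(x, y, xi, config.window, config.degree, weights) for xi in eval_points]
    )


def stl_decompose(
    series,
    period: int = 12,
    seasonal_config: LoessConfig | None = None,
    trend_config: LoessConfig | None = None,
    inner_iterations: int = 5,
    outer_iterations: int = 0,
) -> DecompositionResult:
    """STL decomposition of a monthly series (or plain array) at ``period``.

    Raises :class:`InsufficientDataError` for series shorter than two periods.
    """
    months = None
    if isinstance(series, MonthlySeries):
        months = series.months
        y = series.values
    else:
        y = np.asarray(series, dtype=float)
    n = y.size
    if period < 2:
        raise InvalidArgumentError("period must be >= 2")
    if n < 2 * period:
        raise InsufficientDataError(
            f"series length {n} is shorter than two periods ({2 * period})"
        )
    s_cfg = seasonal_config or default_seasonal_config()
    t_cfg = trend_config or default_trend_config(period, (seasonal_config or default_seasonal_config()).window)
    l_cfg = LoessConfig(window=_lowpass_window(period), degree=1)

    t_axis = np.arange(n, dtype=float)
    trend = np.zeros(n)
    seasonal = np.zeros(n)
    rob = np.ones(n)

    for outer in range(outer_iterations + 1):
        for _ in range(inner_iterations):
            detrended = y - trend
            # 1. cycle-subseries smoothing, extended one period at each end
            cycle = np.empty(n + 2 * period)
            for phase in range(period):
                idx = np.arange(phase, n, period)
                sub = detrended[idx]
                xs = np.arange(sub.size, dtype=float)
                ev = np.arange(-1.0, sub.size + 1.0)
                smoothed = _smooth_weighted(xs, sub, s_cfg, ev, rob[idx])
                cycle[phase::period][: smoothed.size] = smoothed
            # 2. low-pass filter of the extended cycle-subseries
            lp = _moving_average(_moving_average(_moving_average(cycle, period), period), 3)
            low = _smooth_weighted(
                np.arange(lp.size, dtype=float), lp, l_cfg, np.arange(lp.size, dtype=float),
                np.ones(lp.size),
            )
            # 3. seasonal = smoothed cycle-subseries minus its low-pass part
            seasonal = cycle[period : period + n] - low
            # 4. trend from the deseasonalised series
            deseasonalised = y - seasonal
            trend = _smooth_weighted(t_axis, deseasonalised, t_cfg, t_axis, rob)
        if outer < outer_iterations:
            remainder = y - seasonal - trend
            m = np.median(np.abs(remainder))
            if m <= 0:
                break
            rob = _bisquare(remainder / (6.0 * m))

    remainder = y - seasonal - trend  # exact by construction
    return DecompositionResult(
        seasonal=seasonal, trend=trend, remainder=remainder, period=period, months=months
    )


class STLDecomposer:
    """Estimator-style wrapper around :func:`stl_decompose`.

    After :meth:`fit`, the components are available as ``seasonal_``,
    ``trend_`` and ``remainder_``; :meth:`transform` returns the
    deseasonalised series.
    """

    def __init__(
        self,
        period: int = 12,
        seasonal_config: LoessConfig | None = None,
        trend_config: LoessConfig | None = None,
        inner_iterations: int = 5,
        outer_iterations: int = 0,
    ):
        self.period = period
        self.seasonal_config = seasonal_config
        self.trend_config = trend_config
        self.inner_iterations = inner_iterations
        self.outer_iterations = outer_iterations

    def get_params(self, deep: bool = True) -> dict:
        return {
            "period": self.period,
            "seasonal_config": self.seasonal_config,
            "trend_config": self.trend_config,
            "inner_iterations": self.inner_iterations,
            "outer_iterations": self.outer_iterations,
        }

    def set_params(self, **params) -> "STLDecomposer":
        for key, value in params.items():
            if key not in self.get_params():
                raise InvalidArgumentError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, series) -> "STLDecomposer":
        result = stl_decompose(
            series,
            period=self.period,
            seasonal_config=self.seasonal_config,
            trend_config=self.trend_config,
            inner_iterations=self.inner_iterations,
            outer_iterations=self.outer_iterations,
        )
        self.result_ = result
        self.seasonal_ = result.seasonal
        self.trend_ = result.trend
        self.remainder_ = result.remainder
        return self

    def transform(self, series) -> np.ndarray:
        if not hasattr(self, "result_"):
            raise InvalidArgumentError("STLDecomposer must be fitted before transform")
        y = series.values if isinstance(series, MonthlySeries) else np.asarray(series, float)
        return y - self.seasonal_


def stationarity_test(values, alpha: float = 0.05) -> dict:
    """Augmented Dickey-Fuller unit-root test.

    The lag order is selected by AIC up to the Schwert rule maximum
    ``floor(12 (n/100)^{1/4})``; the unit-root null is rejected when the
    MacKinnon p-value falls below ``alpha`` (``stationary=True``).
    """
    from statsmodels.tsa.stattools import adfuller

    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise InsufficientDataError("stationarity test needs at least 10 observations")
    if np.ptp(values) == 0:
        raise DegenerateInputError("stationarity test undefined for a constant sequence")
    maxlag = int(np.floor(12.0 * (values.size / 100.0) ** 0.25))
    maxlag = min(maxlag, values.size // 2 - 2)
    stat, pvalue, usedlag, *_ = adfuller(values, maxlag=maxlag, autolag="AIC")
    return {
        "stationary": bool(pvalue < alpha),
        "statistic": float(stat),
        "p_value_or_bound": float(pvalue),
        "lags_used": int(usedlag),
    }
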