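"""Forecaster contract: scikit-learn-style estimators plus a plug-in adapter.

Every built-in forecaster is an estimator with ``fit(series) -> self`` and
``predict(horizon) -> Forecast`` (interval level is a constructor parameter).
The evaluator consumes :class:`ForecasterAdapter` objects — a name plus a
``fit_and_forecast(series, horizon, seed)`` procedure — so external models
(e.g. a neural network supplied by the user) can be benchmarked alongside
the built-ins without the evaluator knowing anything about them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from sklearn.base import BaseEstimator

from .errors import ContractViolationError, InvalidArgumentError
from .series import Forecast, MonthlySeries


class BaseForecaster(BaseEstimator):
    """Base class for monthly-series forecasters.

    Subclasses implement ``_fit(series)`` and ``_predict(horizon)`` and set
    fitted attributes with a trailing underscore.
    """

    def fit(self, series: MonthlySeries, y=None) -> "BaseForecaster":
        if not isinstance(series, MonthlySeries):
            series = MonthlySeries.from_start("2000-01", series)
        self.series_ = series
        self._fit(series)
        return self

    def predict(self, horizon: int) -> Forecast:
        if not hasattr(self, "series_"):
            raise InvalidArgumentError(f"{type(self).__name__} must be fitted first")
        if horizon <= 0:
            raise InvalidArgumentError("horizon must be positive")
        return self._predict(int(horizon))

    # -- subclass hooks -------------------------------------------------
    def _fit(self, series: MonthlySeries) -> None:  # pragma: no cover - abstract
        raise NotImplementedError

    def _predict(self, horizon: int) -> Forecast:  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass(frozen=True)
class ForecasterAdapter:
    """Named forecasting procedure usable by the cross-validation evaluator.

    ``fit_and_forecast(series, horizon, seed)`` must return a
    :class:`Forecast` of exactly the requested horizon and be deterministic
    for fixed inputs and seed.
    """

    name: str
    fit_and_forecast: Callable[[MonthlySeries, int, int], Forecast]

    def __call__(self, series: MonthlySeries, horizon: int, seed: int = 0) -> Forecast:
        forecast = self.fit_and_forecast(series, horizon, seed)
        if not isinstance(forecast, Forecast):
            raise ContractViolationError(
                f"forecaster {self.name!r} returned {type(forecast).__name__}, not Forecast"
            )
        if forecast.horizon != horizon:
            raise ContractViolationError(
                f"forecaster {self.name!r} returned horizon {forecast.horizon}, "
                f"requested {horizon}"
            )
        return forecast


def wrap_external_forecaster(name: str, procedure) -> ForecasterAdapter:
    """Wrap a ``(series, horizon, seed) -> Forecast`` procedure as an adapter."""
    if not callable(procedure):
        raise InvalidArgumentError("procedure must be callable")
    return ForecasterAdapter(name=name, fit_and_forecast=procedure)


def adapter_from_estimator(name: str, estimator: BaseForecaster) -> ForecasterAdapter:
    """Adapter over an (unfitted) estimator; a fresh clone is fitted per call."""
    from sklearn.base import clone

    def _call(series: MonthlySeries, horizon: int, seed: int) -> Forecast:
        model = clone(estimator)
        if "seed" in model.get_params():
            model.set_params(seed=seed)
        return model.fit(series).predict(horizon)

    return ForecasterAdapter(name=name, fit_and_forecast=_call)
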