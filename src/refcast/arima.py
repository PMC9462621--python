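"""ARIMA(p, d, q) fitting, AIC grid search, forecasting, and the composed
STL + auto-ARIMA pipeline.

The model for the ``d``-times differenced series ``w`` is ARMA with
intercept in mean form::

    (w_t - mu) = phi_1 (w_{t-1} - mu) + ... + phi_p (w_{t-p} - mu)
                 + e_t + theta_1 e_{t-1} + ... + theta_q e_{t-q}

with Gaussian innovations of variance sigma^2.  Estimation maximises the
exact Gaussian likelihood (Kalman filter on the state-space form, variance
concentrated out), started from conditional-sum-of-squares values;
stationarity/invertibility are enforced by the partial-autocorrelation
parametrisation.  Order selection minimises AIC = 2k - 2 loglik with
k = p + q + 2 (intercept and innovation variance both counted).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import optimize, stats

from ._arma import (
    ar_to_pacf,
    css_objective,
    kalman_concentrated_loglik,
    kalman_predicted_state,
    unconstrained_to_coeffs,
)
from .base import BaseForecaster
from .decomposition import stl_decompose, stationarity_test
from .errors import (
    DegenerateInputError,
    FitFailureError,
    InsufficientDataError,
    InvalidArgumentError,
    NoModelError,
)
from .series import Forecast, MonthlySeries

logger = logging.getLogger(__name__)

DEFAULT_GRID = (3, 2, 3)  # p_max, d_max, q_max


@dataclass(frozen=True)
class ArimaOrder:
    p: int
    d: int
    q: int

    def __post_init__(self):
        if self.p < 0 or self.d < 0 or self.q < 0:
            raise InvalidArgumentError("p, d, q must be non-negative")

    @property
    def k(self) -> int:
        """Parameter count for AIC: AR + MA + intercept + variance."""
        return self.p + self.q + 2


@dataclass(frozen=True)
class ArimaFit:
    """A fitted ARIMA model on the differenced scale."""

    order: ArimaOrder
    ar_coefficients: np.ndarray
    ma_coefficients: np.ndarray
    intercept: float
    innovation_variance: float
    log_likelihood: float
    aic: float
    n_observations: int

    @property
    def ar_inverse_roots(self) -> np.ndarray:
        if self.order.p == 0:
            return np.empty(0, dtype=complex)
        # z^p phi(1/z) = z^p - phi_1 z^{p-1} - ... - phi_p
        return np.roots(np.r_[1.0, -np.asarray(self.ar_coefficients)])

    @property
    def ma_inverse_roots(self) -> np.ndarray:
        if self.order.q == 0:
            return np.empty(0, dtype=complex)
        # z^q theta(1/z) = z^q + theta_1 z^{q-1} + ... + theta_q
        return np.roots(np.r_[1.0, np.asarray(self.ma_coefficients)])

    @property
    def near_unit_root(self) -> bool:
        """True when the fitted AR polynomial has a root close to the unit circle."""
        if self.order.p == 0:
            return False
        return bool(np.any(np.abs(self.ar_inverse_roots) > 0.99))

    def is_admissible(self, unit_root_tol: float = 0.99,
                      common_factor_tol: float = 0.05) -> bool:
        """Admissibility guard for order selection.

        Over-specified ARMA models are weakly identified: the likelihood
        develops spurious spikes where an AR root sits on the unit circle or
        nearly cancels an MA root (the model then reduces to a smaller order
        already present in the grid).  Such fits are rejected rather than
        allowed to win the AIC comparison.
        """
        ar = self.ar_inverse_roots
        ma = self.ma_inverse_roots
        if ar.size and np.any(np.abs(ar) > unit_root_tol):
            return False
        if ma.size and np.any(np.abs(ma) > unit_root_tol):
            return False
        if ar.size and ma.size:
            dist = np.abs(ar[:, None] - ma[None, :])
            if dist.min() < common_factor_tol:
                return False
        return True


def difference(values, d: int):
    """d-th order difference; length shrinks by d."""
    values = np.asarray(values, dtype=float)
    if d < 0:
        raise InvalidArgumentError("d must be non-negative")
    if d >= values.size:
        raise InsufficientDataError(f"cannot difference {values.size} points {d} times")
    for _ in range(d):
        values = np.diff(values)
    return values


def _min_obs(p: int, q: int) -> int:
    # enough observations to identify every coefficient, the intercept and
    # the variance with a little slack
    return max(3 * (p + q + 1), p + q + 3)


def _css_start(w: np.ndarray, p: int, q: int) -> np.ndarray:
    """Unconstrained starting values from a coarse CSS grid + Yule-Walker AR."""
    x = w - w.mean()
    u0 = np.zeros(p + q)
    if p > 0:
        # Yule-Walker estimates, pulled inside the stationary region
        r = np.array([np.dot(x[: x.size - k], x[k:]) / x.size for k in range(p + 1)])
        if r[0] > 0:
            import numpy.linalg as la

            R = np.empty((p, p))
            for i in range(p):
                for j in range(p):
                    R[i, j] = r[abs(i - j)]
            try:
                phi = la.solve(R, r[1:])
                pac = np.clip(ar_to_pacf(np.ascontiguousarray(phi)), -0.95, 0.95)
                u0[:p] = np.arctanh(pac)
            except la.LinAlgError:
                pass
    return u0


def fit_arima(values, order: ArimaOrder | tuple) -> ArimaFit:
    """Fit ARIMA(p, d, q) with intercept by exact Gaussian maximum likelihood."""
    if not isinstance(order, ArimaOrder):
        order = ArimaOrder(*order)
    p, d, q = order.p, order.d, order.q
    w = difference(values, d)
    n = w.size
    if n < _min_obs(p, q):
        raise InsufficientDataError(
            f"order {(p, d, q)} needs at least {_min_obs(p, q)} observations "
            f"after differencing, got {n}"
        )
    if np.ptp(w) == 0 and (p > 0 or q > 0):
        raise DegenerateInputError("constant differenced series: ARMA undefined")

    if p == 0 and q == 0:
        mu = float(w.mean())
        sigma2 = float(np.mean((w - mu) ** 2))
        if sigma2 <= 0:
            sigma2 = 1e-12
        loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        return ArimaFit(
            order=order,
            ar_coefficients=np.empty(0),
            ma_coefficients=np.empty(0),
            intercept=mu,
            innovation_variance=sigma2,
            log_likelihood=float(loglik),
            aic=float(2 * order.k - 2 * loglik),
            n_observations=n,
        )

    scale = w.std() or 1.0

    def unpack(params):
        u_ar = np.ascontiguousarray(params[:p])
        u_ma = np.ascontiguousarray(params[p : p + q])
        mu = params[p + q] * scale
        phi = unconstrained_to_coeffs(u_ar) if p else np.empty(0)
        # invertibility of 1 + theta_1 B + ... is the stationarity constraint
        # on the sign-flipped coefficients
        theta = -unconstrained_to_coeffs(u_ma) if q else np.empty(0)
        return phi, theta, mu

    def negloglik(params):
        phi, theta, mu = unpack(params)
        ll, _ = kalman_concentrated_loglik(np.ascontiguousarray(w - mu), phi, theta)
        if not np.isfinite(ll):
            return 1e10
        return -ll

    u0 = _css_start(w, p, q)
    start = np.r_[u0, w.mean() / scale]

    # refine starting values by a cheap CSS pass before the exact likelihood
    def css_neg(params):
        phi, theta, mu = unpack(params)
        return css_objective(np.ascontiguousarray(w - mu), phi, theta)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pre = optimize.minimize(css_neg, start, method="Nelder-Mead",
                                options={"maxiter": 200, "xatol": 1e-4, "fatol": 1e-6})
        if np.isfinite(pre.fun):
            start = pre.x
        res = optimize.minimize(
            negloglik, start, method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-10, "gtol": 1e-8},
        )
        if not np.isfinite(res.fun) or res.fun >= 1e10:
            res = optimize.minimize(negloglik, start, method="Nelder-Mead",
                                    options={"maxiter": 2000})
    if not np.isfinite(res.fun) or res.fun >= 1e10:
        raise FitFailureError(f"likelihood optimisation failed for order {(p, d, q)}",
                              order=order)

    phi, theta, mu = unpack(res.x)
    loglik, sigma2 = kalman_concentrated_loglik(np.ascontiguousarray(w - mu), phi, theta)
    if not np.isfinite(loglik):
        raise FitFailureError(f"non-finite likelihood at optimum for order {(p, d, q)}",
                              order=order)
    fit = ArimaFit(
        order=order,
        ar_coefficients=phi,
        ma_coefficients=theta,
        intercept=float(mu),
        innovation_variance=float(sigma2),
        log_likelihood=float(loglik),
        aic=float(2 * order.k - 2 * loglik),
        n_observations=n,
    )
    if fit.near_unit_root:
        logger.debug("order %s: fitted AR polynomial near the unit circle", (p, d, q))
    return fit


def select_differencing_order(values, d_max: int = 2, alpha: float = 0.05) -> int:
    """Smallest d for which the d-times differenced series tests stationary.

    AIC values are not comparable across differencing orders (the effective
    sample and the modelled quantity change), so d is settled first by
    repeated unit-root testing, as in standard automated ARIMA practice.
    A constant after differencing counts as stationary.
    """
    w = np.asarray(values, dtype=float)
    for d in range(d_max + 1):
        try:
            if stationarity_test(w)["stationary"]:
                return d
        except (DegenerateInputError, InsufficientDataError):
            return d
        if d < d_max:
            w = np.diff(w)
    return d_max


def auto_arima_grid_search(values, grid: tuple = DEFAULT_GRID,
                           fixed_d: int | None = None) -> ArimaFit:
    """Fit every (p, d, q) in the grid; return the minimum-AIC fit.

    With ``fixed_d`` the differencing degree is held at that value and only
    p and q are searched.

    Orders that cannot be fitted (too little data, non-convergence) or whose
    fit is inadmissible (root on the unit circle, near-cancelling AR/MA
    factor — see :meth:`ArimaFit.is_admissible`) are skipped.  Ties are
    broken by fewest parameters, then lexicographic (p, d, q).
    """
    p_max, d_max, q_max = grid
    d_values = range(d_max + 1) if fixed_d is None else [fixed_d]
    fits: list[ArimaFit] = []
    for d, p, q in product(d_values, range(p_max + 1), range(q_max + 1)):
        try:
            fit = fit_arima(values, ArimaOrder(p, d, q))
        except (InsufficientDataError, FitFailureError, DegenerateInputError) as exc:
            logger.debug("grid search skipping (%d,%d,%d): %s", p, d, q, exc)
            continue
        if not fit.is_admissible():
            logger.debug("grid search rejecting inadmissible fit (%d,%d,%d)", p, d, q)
            continue
        fits.append(fit)
    if not fits:
        raise NoModelError(f"no order in grid {grid} could be fitted")
    fits.sort(
        key=lambda f: (round(f.aic, 10), f.order.k, (f.order.p, f.order.d, f.order.q))
    )
    return fits[0]


def _psi_weights(fit: ArimaFit, horizon: int) -> np.ndarray:
    """MA-infinity weights of the full ARIMA (differencing folded into the AR part)."""
    p, d, q = fit.order.p, fit.order.d, fit.order.q
    ar = np.r_[1.0, -np.asarray(fit.ar_coefficients)] if p else np.array([1.0])
    diff_poly = np.array([1.0])
    for _ in range(d):
        diff_poly = np.convolve(diff_poly, np.array([1.0, -1.0]))
    ar_star = np.convolve(ar, diff_poly)  # coefficients of phi*(B)(= 1 - a1 B - ...)
    a = -ar_star[1:]  # recursion coefficients
    theta = np.asarray(fit.ma_coefficients)
    psi = np.zeros(horizon)
    psi0 = 1.0
    for j in range(1, horizon):
        acc = theta[j - 1] if j - 1 < theta.size else 0.0
        for i in range(1, min(j, a.size) + 1):
            prev = psi0 if j - i == 0 else psi[j - i]
            acc += a[i - 1] * prev
        psi[j] = acc
    psi[0] = psi0
    return psi


def _point_forecast_differenced(fit: ArimaFit, w: np.ndarray, horizon: int) -> np.ndarray:
    """h-step forecasts of the (differenced) ARMA via the filtered state."""
    from ._arma import arma_state_space

    phi = np.ascontiguousarray(fit.ar_coefficients)
    theta = np.ascontiguousarray(fit.ma_coefficients)
    if fit.order.p == 0 and fit.order.q == 0:
        return np.full(horizon, fit.intercept)
    a = kalman_predicted_state(np.ascontiguousarray(w - fit.intercept), phi, theta)
    T, _ = arma_state_space(phi, theta)
    out = np.empty(horizon)
    for h in range(horizon):
        out[h] = fit.intercept + a[0]
        a = T @ a
    return out


def forecast_arima(fit: ArimaFit, history, horizon: int, level: float = 0.95) -> Forecast:
    """Point and interval forecasts from a fitted ARIMA model.

    Interval half-widths use the cumulative psi-weight variance on the
    original (integrated) scale with a Gaussian quantile at ``level``.
    """
    if horizon <= 0:
        raise InvalidArgumentError("horizon must be positive")
    history = np.asarray(history, dtype=float)
    d = fit.order.d
    w = difference(history, d)
    pred_w = _point_forecast_differenced(fit, w, horizon)
    # integrate back d times
    preds = pred_w
    if d > 0:
        diffs = [history]
        for j in range(1, d):
            diffs.append(np.diff(diffs[-1]))
        for j in range(d - 1, -1, -1):
            preds = diffs[j][-1] + np.cumsum(preds)
    psi = _psi_weights(fit, horizon)
    var = fit.innovation_variance * np.cumsum(psi**2)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return Forecast(horizon=horizon, point=preds, lower=preds - half,
                    upper=preds + half, level=level)


def stl_arima_forecast(
    series: MonthlySeries,
    horizon: int,
    grid: tuple = DEFAULT_GRID,
    level: float = 0.95,
    period: int = 12,
) -> Forecast:
    """The composed STL + auto-ARIMA forecaster.

    The series is decomposed at the seasonal period; the seasonal component
    is extended by repeating its last full cycle (seasonal-naive), while the
    trend and remainder are each forecast by an AIC grid-searched ARIMA.
    The recomposed point forecast is the sum; interval variance is the sum
    of the trend and remainder forecast variances (components treated as
    independent).  Short series (< 2 seasonal cycles) fall back to a raw
    auto-ARIMA with a logged warning.
    """
    if horizon <= 0:
        raise InvalidArgumentError("horizon must be positive")
    if horizon > 2 * period:
        logger.warning("forecast horizon %d exceeds two seasonal cycles", horizon)
    y = series.values if isinstance(series, MonthlySeries) else np.asarray(series, float)

    def _fallback() -> Forecast:
        fit = auto_arima_grid_search(y, grid)
        return forecast_arima(fit, y, horizon, level)

    if y.size < 2 * period:
        logger.warning(
            "series length %d < %d months: falling back to auto-ARIMA on the raw series",
            y.size, 2 * period,
        )
        return _fallback()
    try:
        decomp = stl_decompose(series if isinstance(series, MonthlySeries) else y,
                               period=period)
    except (InsufficientDataError, InvalidArgumentError) as exc:
        logger.warning("decomposition degenerate (%s); falling back to raw auto-ARIMA", exc)
        return _fallback()

    # the smoothed trend is usually non-stationary: settle its differencing
    # degree by unit-root testing, then grid-search p and q at that degree
    trend_d = select_differencing_order(decomp.trend, d_max=grid[1])

    # seasonal-naive extension of the last full cycle
    last_cycle = decomp.seasonal[-period:]
    seasonal_fc = np.tile(last_cycle, int(np.ceil(horizon / period)))[:horizon]

    z = stats.norm.ppf(0.5 + level / 2.0)
    total_var = np.zeros(horizon)
    total_point = seasonal_fc.copy()
    for component, fixed_d in ((decomp.trend, trend_d), (decomp.remainder, None)):
        try:
            fit = auto_arima_grid_search(component, grid, fixed_d=fixed_d)
        except NoModelError:
            logger.warning("no ARIMA model for a component; falling back to raw series")
            return _fallback()
        fc = forecast_arima(fit, component, horizon, level)
        total_point += fc.point
        total_var += ((fc.upper - fc.lower) / (2.0 * z)) ** 2
    half = z * np.sqrt(total_var)
    return Forecast(horizon=horizon, point=total_point, lower=total_point - half,
                    upper=total_point + half, level=level)


# ---------------------------------------------------------------------------
# estimator classes


class ArimaForecaster(BaseForecaster):
    """ARIMA(p, d, q) with a fixed order."""

    def __init__(self, p: int = 1, d: int = 0, q: int = 0, level: float = 0.95):
        self.p = p
        self.d = d
        self.q = q
        self.level = level

    def _fit(self, series: MonthlySeries) -> None:
        self.fit_ = fit_arima(series.values, ArimaOrder(self.p, self.d, self.q))

    def _predict(self, horizon: int) -> Forecast:
        return forecast_arima(self.fit_, self.series_.values, horizon, self.level)


class AutoArimaForecaster(BaseForecaster):
    """AIC grid-searched ARIMA over orders p <= p_max, d <= d_max, q <= q_max."""

    def __init__(self, p_max: int = 3, d_max: int = 2, q_max: int = 3,
                 level: float = 0.95):
        self.p_max = p_max
        self.d_max = d_max
        self.q_max = q_max
        self.level = level

    def _fit(self, series: MonthlySeries) -> None:
        self.fit_ = auto_arima_grid_search(series.values,
                                           (self.p_max, self.d_max, self.q_max))

    def _predict(self, horizon: int) -> Forecast:
        return forecast_arima(self.fit_, self.series_.values, horizon, self.level)


class StlArimaForecaster(BaseForecaster):
    """STL decomposition followed by per-component auto-ARIMA (the headline model)."""

    def __init__(self, period: int = 12, p_max: int = 3, d_max: int = 2,
                 q_max: int = 3, level: float = 0.95):
        self.period = period
        self.p_max = p_max
        self.d_max = d_max
        self.q_max = q_max
        self.level = level

    def _fit(self, series: MonthlySeries) -> None:
        pass  # all work happens at predict time (decomposition + component fits)

    def _predict(self, horizon: int) -> Forecast:
        return stl_arima_forecast(
            self.series_, horizon,
            grid=(self.p_max, self.d_max, self.q_max),
            level=self.level, period=self.period,
        )
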