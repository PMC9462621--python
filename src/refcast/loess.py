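"""Locally weighted polynomial regression (loess).

The smoothing primitive the seasonal-trend decomposition is built from:
at each evaluation point a polynomial of low degree is fitted by weighted
least squares to the ``window`` nearest observations, with tricube
neighbourhood weights.  Optional robustness iterations downweight points
with large residuals using bisquare weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidConfigError, InvalidArgumentError


@dataclass(frozen=True)
class LoessConfig:
    """Smoother parameters: neighbourhood size, polynomial degree, robustness."""

    window: int
    degree: int = 1
    robustness_iterations: int = 0

    def __post_init__(self):
        if self.degree not in (0, 1, 2):
            raise InvalidConfigError("degree must be 0, 1 or 2")
        if self.window < self.degree + 2:
            raise InvalidConfigError(
                f"window ({self.window}) must be >= degree + 2 ({self.degree + 2})"
            )
        if self.window % 2 == 0:
            raise InvalidConfigError("window must be odd")
        if self.robustness_iterations < 0:
            raise InvalidConfigError("robustness_iterations must be non-negative")


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def _bisquare(u: np.ndarray) -> np.ndarray:
    return np.clip(1.0 - u**2, 0.0, None) ** 2


def _fit_at(
    x: np.ndarray,
    y: np.ndarray,
    x0: float,
    window: int,
    degree: int,
    rob_weights: np.ndarray,
) -> float:
    n = x.size
    q = min(window, n)
    dist = np.abs(x - x0)
    # q-th smallest distance defines the bandwidth; for window > n the
    # bandwidth is inflated by window/n (standard loess convention).
    if window <= n:
        lam = np.partition(dist, q - 1)[q - 1]
    else:
        lam = dist.max() * window / n
    if lam <= 0:
        # all neighbours at x0 itself: weighted mean of exact matches
        mask = dist == 0
        return float(np.average(y[mask], weights=np.maximum(rob_weights[mask], 1e-12)))
    w = _tricube(dist / lam) * rob_weights
    mask = w > 0
    if mask.sum() == 0:  # all robustness weights vanished; fall back to tricube
        w = _tricube(dist / lam)
        mask = w > 0
    xw, yw, ww = x[mask], y[mask], w[mask]
    deg = min(degree, xw.size - 1)
    # centred design for conditioning
    xc = xw - x0
    cols = [np.ones_like(xc)]
    for d in range(1, deg + 1):
        cols.append(xc**d)
    X = np.column_stack(cols)
    sw = np.sqrt(ww)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], yw * sw, rcond=None)
    return float(beta[0])  # polynomial evaluated at x0


def loess_smooth(
    x,
    y,
    config: LoessConfig,
    eval_points=None,
) -> np.ndarray:
    """Loess smooth of ``y`` over ``x`` evaluated at ``eval_points``.

    ``x`` must be strictly increasing.  With ``robustness_iterations > 0``
    the fit is repeated with bisquare weights ``(1 - (r / 6 m)^2)^2`` where
    ``m`` is the median absolute residual.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InvalidArgumentError("x and y must have equal length")
    if x.size == 0:
        raise InvalidArgumentError("empty input")
    if np.any(np.diff(x) <= 0):
        raise InvalidArgumentError("x must be strictly increasing")
    if eval_points is None:
        eval_points = x
    eval_points = np.asarray(eval_points, dtype=float)

    rob = np.ones_like(y)
    for iteration in range(config.robustness_iterations + 1):
        fitted_at_x = None
        if iteration < config.robustness_iterations:
            fitted_at_x = np.array(
                [_fit_at(x, y, xi, config.window, config.degree, rob) for xi in x]
            )
            resid = y - fitted_at_x
            m = np.median(np.abs(resid))
            if m <= 0:
                break
            rob = _bisquare(resid / (6.0 * m))
    out = np.array(
        [_fit_at(x, y, xi, config.window, config.degree, rob) for xi in eval_points]
    )
    return out
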