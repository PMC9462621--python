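"""Numerical kernels for Gaussian ARMA likelihood evaluation.

The exact likelihood is computed with a Kalman filter on the Harvey
state-space form of the ARMA(p, q) model (state dimension
``r = max(p, q + 1)``), with the innovation variance concentrated out.
Stationarity and invertibility are enforced during optimisation by the
partial-autocorrelation parametrisation (hyperbolic-tangent map followed by
the Durbin-Levinson recursion).

The time loop is compiled with numba; everything here is private API.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def pacf_to_ar(pacf: np.ndarray) -> np.ndarray:
    """Durbin-Levinson map from partial autocorrelations to AR coefficients."""
    p = pacf.size
    a = np.zeros(p)
    for k in range(p):
        a_new = a.copy()
        a_new[k] = pacf[k]
        for i in range(k):
            a_new[i] = a[i] - pacf[k] * a[k - 1 - i]
        a = a_new
    return a


@njit(cache=True)
def ar_to_pacf(ar: np.ndarray) -> np.ndarray:
    """Inverse Durbin-Levinson map (AR coefficients to partial autocorrelations)."""
    p = ar.size
    a = ar.copy()
    pacf = np.zeros(p)
    for k in range(p - 1, -1, -1):
        pacf[k] = a[k]
        denom = 1.0 - a[k] * a[k]
        if abs(denom) < 1e-12:
            denom = 1e-12 if denom >= 0 else -1e-12
        a_prev = np.zeros(p)
        for i in range(k):
            a_prev[i] = (a[i] + a[k] * a[k - 1 - i]) / denom
        a = a_prev
    return pacf


@njit(cache=True)
def unconstrained_to_coeffs(u: np.ndarray) -> np.ndarray:
    """tanh map to (-1, 1) partial autocorrelations, then Durbin-Levinson.

    The map is clamped slightly inside the open interval so the implied
    state covariance stays solvable at extreme optimiser iterates.
    """
    return pacf_to_ar(0.9999 * np.tanh(u))


@njit(cache=True)
def _stationary_initial_cov(T: np.ndarray, RR: np.ndarray) -> np.ndarray:
    """Solve P = T P T' + RR' via the vectorised linear system."""
    r = T.shape[0]
    r2 = r * r
    A = np.eye(r2) - np.kron(T, T)
    b = RR.flatten().astype(np.float64)
    # lstsq never raises on (near-)singular systems; the caller rejects
    # non-finite covariances by returning -inf likelihood
    vec = np.linalg.lstsq(A, b)[0]
    return vec.reshape((r, r))


@njit(cache=True)
def arma_state_space(phi: np.ndarray, theta: np.ndarray):
    """Harvey form: transition T, disturbance loading R (unit variance)."""
    p = phi.size
    q = theta.size
    r = max(p, q + 1)
    T = np.zeros((r, r))
    for i in range(p):
        T[i, 0] = phi[i]
    for i in range(r - 1):
        T[i, i + 1] = 1.0
    R = np.zeros(r)
    R[0] = 1.0
    for i in range(q):
        R[i + 1] = theta[i]
    return T, R


@njit(cache=True)
def kalman_concentrated_loglik(x: np.ndarray, phi: np.ndarray, theta: np.ndarray):
    """Concentrated Gaussian log-likelihood of a zero-mean ARMA(p, q).

    Returns ``(loglik, sigma2_hat)``; ``(-inf, nan)`` on numerical failure.
    """
    n = x.size
    T, R = arma_state_space(phi, theta)
    r = T.shape[0]
    RR = np.outer(R, R)
    P = _stationary_initial_cov(T, RR)
    if not np.all(np.isfinite(P)):
        return -np.inf, np.nan
    a = np.zeros(r)
    sum_log_f = 0.0
    ssq = 0.0
    for t in range(n):
        f = P[0, 0]
        if f < 1e-300 or not np.isfinite(f):
            return -np.inf, np.nan
        v = x[t] - a[0]
        sum_log_f += np.log(f)
        ssq += v * v / f
        # a_{t+1|t} = T a + T P z v / f ;  P_{t+1|t} = T (P - P z z' P / f) T' + RR'
        Pz = P[:, 0].copy()
        a_new = T @ a + (T @ Pz) * (v / f)
        P_upd = P - np.outer(Pz, Pz) / f
        P = T @ P_upd @ T.T + RR
        a = a_new
    sigma2 = ssq / n
    if sigma2 <= 0 or not np.isfinite(sigma2):
        return -np.inf, np.nan
    loglik = -0.5 * n * (np.log(2.0 * np.pi) + 1.0 + np.log(sigma2)) - 0.5 * sum_log_f
    return loglik, sigma2


@njit(cache=True)
def kalman_predicted_state(x: np.ndarray, phi: np.ndarray, theta: np.ndarray):
    """Filter the full sample; return the predicted state a_{n+1|n}."""
    n = x.size
    T, R = arma_state_space(phi, theta)
    r = T.shape[0]
    RR = np.outer(R, R)
    P = _stationary_initial_cov(T, RR)
    a = np.zeros(r)
    for t in range(n):
        f = P[0, 0]
        if f < 1e-300:
            f = 1e-300
        v = x[t] - a[0]
        Pz = P[:, 0].copy()
        a = T @ a + (T @ Pz) * (v / f)
        P = T @ (P - np.outer(Pz, Pz) / f) @ T.T + RR
    return a


@njit(cache=True)
def css_objective(x: np.ndarray, phi: np.ndarray, theta: np.ndarray) -> float:
    """Conditional sum of squares (zeros initialisation) — starting values only."""
    n = x.size
    p = phi.size
    q = theta.size
    e = np.zeros(n)
    ssq = 0.0
    for t in range(n):
        pred = 0.0
        for i in range(p):
            if t - 1 - i >= 0:
                pred += phi[i] * x[t - 1 - i]
        for j in range(q):
            if t - 1 - j >= 0:
                pred += theta[j] * e[t - 1 - j]
        e[t] = x[t] - pred
        ssq += e[t] * e[t]
    return ssq
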