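"""Synthetic referral data with the statistical structure the analysis assumes.

Two generators are provided:

* :func:`generate_monthly_series` draws a monthly count series from a
  log-linear rate model — baseline rate, linear trend on the log scale,
  yearly (period-12) Fourier seasonality, an optional multiplicative level
  shift over a closed month window (the lockdown shock), and Poisson or
  negative-binomial observation noise.
* :func:`generate_referral_records` draws individual referral records
  (date, referrer grade, specialty, urgency, Glasgow Coma Score, symptom
  duration, referring site) from per-period categorical profiles.

Both are deterministic under a fixed seed.  :func:`aggregate_records_to_series`
bins records into calendar months, the discretisation the forecasting stage
operates on.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, InvalidConfigError
from .series import MonthlySeries

GRADES = ("intern", "resident", "attending", "other")
URGENCIES = ("urgent", "emergency")


@dataclass(frozen=True)
class SeriesGeneratorConfig:
    """Data-generating assumptions for a monthly referral-count series.

    The expected count at month ``t`` (0-based) is::

        exp(baseline_log_rate + trend_per_month * t
            + sum_k [a_k cos(2 pi k t / 12) + b_k sin(2 pi k t / 12)]
            + shock_log_effect * 1[t in shock_window])

    ``seasonal_amplitudes`` is a list of ``(harmonic k, cosine coeff a_k,
    sine coeff b_k)`` triples on the log-rate scale.  ``shock_window`` is a
    closed ``(start, end)`` pair of ``'YYYY-MM'`` months inside the span.

    The defaults are calibrated to the referral cohort the generator
    emulates: exponential growth giving yearly median volumes of ~8
    (2019-20), ~13 (2021) and ~17-18 over the following forecast year, a
    multiplicative dip of 0.75 over the UK lockdown window (so the lockdown
    year's median stays ~8 instead of the trend-implied ~10.5), mild yearly
    seasonality, and ~460 referrals over the 89-month span.
    """

    start_month: str = "2014-06"
    n_months: int = 89
    baseline_log_rate: float = 0.623   # ~1.9 referrals/month at mid-2014
    trend_per_month: float = 0.0231    # doubles roughly every 2.5 years
    seasonal_amplitudes: tuple = ((1, 0.10, 0.05),)
    shock_window: tuple | None = ("2020-03", "2021-02")
    shock_log_effect: float = float(np.log(0.75))
    noise: str = "poisson"
    dispersion: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_months <= 0:
            raise InvalidConfigError("n_months must be positive")
        if self.noise not in ("poisson", "negative_binomial"):
            raise InvalidConfigError(f"unknown noise model {self.noise!r}")
        if self.noise == "negative_binomial" and self.dispersion <= 0:
            raise InvalidConfigError("dispersion must be positive")
        for harm in self.seasonal_amplitudes:
            if len(harm) != 3 or int(harm[0]) < 1:
                raise InvalidConfigError(
                    "seasonal_amplitudes entries must be (harmonic>=1, cos, sin)"
                )
        if self.shock_window is not None:
            start = pd.Period(self.start_month, freq="M")
            lo = pd.Period(self.shock_window[0], freq="M")
            hi = pd.Period(self.shock_window[1], freq="M")
            if not (start <= lo <= hi <= start + self.n_months - 1):
                raise InvalidConfigError("shock_window must lie inside the series span")


def expected_rates(config: SeriesGeneratorConfig) -> np.ndarray:
    """Analytic expected count per month under ``config`` (no noise)."""
    t = np.arange(config.n_months, dtype=float)
    log_rate = config.baseline_log_rate + config.trend_per_month * t
    for k, a, b in config.seasonal_amplitudes:
        ang = 2.0 * np.pi * int(k) * t / 12.0
        log_rate += a * np.cos(ang) + b * np.sin(ang)
    if config.shock_window is not None:
        months = pd.period_range(config.start_month, periods=config.n_months, freq="M")
        lo = pd.Period(config.shock_window[0], freq="M")
        hi = pd.Period(config.shock_window[1], freq="M")
        log_rate = log_rate + config.shock_log_effect * (
            (months >= lo) & (months <= hi)
        ).astype(float)
    return np.exp(log_rate)


def generate_monthly_series(config: SeriesGeneratorConfig) -> MonthlySeries:
    """Draw a monthly count series from the configured rate model."""
    rates = expected_rates(config)
    rng = np.random.default_rng(config.seed)
    if config.noise == "poisson":
        counts = rng.poisson(rates)
    else:
        # NB2 parametrisation: mean mu, variance mu + mu^2 / dispersion
        r = config.dispersion
        p = r / (r + rates)
        counts = rng.negative_binomial(r, p)
    return MonthlySeries.from_start(config.start_month, counts)


@dataclass(frozen=True)
class ReferralRecord:
    """One acute referral as received by the on-call neurosurgical service."""

    referral_date: _dt.date
    grade: str
    specialty: str
    urgency: str
    gcs: int
    symptom_duration_days: int
    site_id: str

    def __post_init__(self):
        if self.grade not in GRADES:
            raise InvalidArgumentError(f"grade must be one of {GRADES}, got {self.grade!r}")
        if self.urgency not in URGENCIES:
            raise InvalidArgumentError(
                f"urgency must be one of {URGENCIES}, got {self.urgency!r}"
            )
        if not 3 <= int(self.gcs) <= 15:
            raise InvalidArgumentError(f"gcs must lie in [3, 15], got {self.gcs}")
        if int(self.symptom_duration_days) < 1:
            raise InvalidArgumentError("symptom_duration_days must be >= 1")


@dataclass(frozen=True)
class PeriodProfile:
    """Categorical marginals for referrals generated within one period.

    ``grade_probs`` / ``urgency_probs`` follow the order of :data:`GRADES`
    and :data:`URGENCIES`.  GCS is drawn from ``gcs_probs`` over 3..15;
    symptom duration is geometric with mean ``symptom_duration_mean`` days
    (support starting at 1).  Sites and specialties are uniform over the
    given label pools.
    """

    start_month: str
    end_month: str
    grade_probs: tuple = (0.28, 0.62, 0.10, 0.0)
    urgency_probs: tuple = (0.70, 0.30)
    gcs_probs: tuple | None = None
    symptom_duration_mean: float = 10.0
    n_sites: int = 10
    specialties: tuple = ("emergency medicine", "endocrinology", "ophthalmology", "other")

    def __post_init__(self):
        for name, probs, labels in (
            ("grade_probs", self.grade_probs, GRADES),
            ("urgency_probs", self.urgency_probs, URGENCIES),
        ):
            probs = np.asarray(probs, dtype=float)
            if probs.size != len(labels) or np.any(probs < 0):
                raise InvalidConfigError(f"{name} must be {len(labels)} non-negative values")
            if abs(probs.sum() - 1.0) > 1e-6:
                raise InvalidConfigError(f"{name} must sum to 1, got {probs.sum():.6f}")
        if self.gcs_probs is not None:
            g = np.asarray(self.gcs_probs, dtype=float)
            if g.size != 13 or abs(g.sum() - 1.0) > 1e-6 or np.any(g < 0):
                raise InvalidConfigError("gcs_probs must be 13 probabilities over 3..15")
        if self.symptom_duration_mean < 1:
            raise InvalidConfigError("symptom_duration_mean must be >= 1 day")


def _default_gcs_probs() -> np.ndarray:
    # Mass concentrated at 14-15 (mean ~14.8, small SD), a light left tail.
    probs = np.zeros(13)
    probs[-1] = 0.80   # GCS 15
    probs[-2] = 0.12   # GCS 14
    probs[-3] = 0.04   # GCS 13
    probs[:-3] = 0.04 / 10.0
    return probs / probs.sum()


def generate_referral_records(
    n: int, period_profiles: list[PeriodProfile], seed: int
) -> list[ReferralRecord]:
    """Draw ``n`` referral records per profile period.

    ``n`` is the number of records per period; dates are uniform within each
    period's month window.
    """
    if n <= 0:
        raise InvalidConfigError("n must be positive")
    if not period_profiles:
        raise InvalidConfigError("at least one period profile is required")
    rng = np.random.default_rng(seed)
    records: list[ReferralRecord] = []
    for profile in period_profiles:
        start = pd.Period(profile.start_month, freq="M").start_time.date()
        end = pd.Period(profile.end_month, freq="M").end_time.date()
        span_days = (end - start).days + 1
        gcs_probs = (
            np.asarray(profile.gcs_probs, dtype=float)
            if profile.gcs_probs is not None
            else _default_gcs_probs()
        )
        day_offsets = rng.integers(0, span_days, size=n)
        grades = rng.choice(len(GRADES), size=n, p=np.asarray(profile.grade_probs, float))
        urgencies = rng.choice(2, size=n, p=np.asarray(profile.urgency_probs, float))
        gcs = rng.choice(np.arange(3, 16), size=n, p=gcs_probs)
        durations = rng.geometric(1.0 / max(profile.symptom_duration_mean, 1.0), size=n)
        sites = rng.integers(0, profile.n_sites, size=n)
        specs = rng.choice(len(profile.specialties), size=n)
        for i in range(n):
            records.append(
                ReferralRecord(
                    referral_date=start + _dt.timedelta(days=int(day_offsets[i])),
                    grade=GRADES[grades[i]],
                    specialty=profile.specialties[specs[i]],
                    urgency=URGENCIES[urgencies[i]],
                    gcs=int(gcs[i]),
                    symptom_duration_days=int(durations[i]),
                    site_id=f"site_{sites[i]:02d}",
                )
            )
    records.sort(key=lambda r: r.referral_date)
    return records


def aggregate_records_to_series(
    records: list[ReferralRecord],
    span: tuple[str, str],
    truncate: bool = False,
) -> MonthlySeries:
    """Count records per calendar month over ``span = (first, last)`` months.

    Months with no records appear with count 0.  Records outside the span
    raise unless ``truncate=True`` explicitly requests dropping them.
    """
    lo = pd.Period(span[0], freq="M")
    hi = pd.Period(span[1], freq="M")
    if hi < lo:
        raise InvalidArgumentError(f"empty span {span[0]}..{span[1]}")
    months = pd.period_range(lo, hi, freq="M")
    counts = np.zeros(months.size, dtype=np.int64)
    for rec in records:
        period = pd.Period(rec.referral_date, freq="M")
        if period < lo or period > hi:
            if truncate:
                continue
            raise InvalidArgumentError(
                f"record dated {rec.referral_date} lies outside span "
                f"{span[0]}..{span[1]}; pass truncate=True to drop it"
            )
        counts[period.ordinal - lo.ordinal] += 1
    return MonthlySeries(months, counts)
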