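"""CSV readers and writers for referral records, series and forecasts.

All tabular interchange is plain CSV with headers; dates are ISO-8601 and
months are ``YYYY-MM``.  Readers validate every row against the type
invariants and report offending line numbers.
"""

from __future__ import annotations

import datetime as _dt
import logging

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, SchemaError
from .series import Forecast, MonthlySeries
from .synthetic import ReferralRecord

logger = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "referral_date", "grade", "specialty", "urgency", "gcs",
    "symptom_duration_days", "site_id",
]


def write_records_csv(records: list[ReferralRecord], path) -> None:
    rows = [
        {
            "referral_date": rec.referral_date.isoformat(),
            "grade": rec.grade,
            "specialty": rec.specialty,
            "urgency": rec.urgency,
            "gcs": rec.gcs,
            "symptom_duration_days": rec.symptom_duration_days,
            "site_id": rec.site_id,
        }
        for rec in records
    ]
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False)


def read_referrals_csv(path) -> list[ReferralRecord]:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    records = []
    errors = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            date = _dt.date.fromisoformat(str(row["referral_date"]))
        except ValueError:
            errors.append(f"line {line}: unparseable date {row['referral_date']!r}")
            continue
        try:
            records.append(
                ReferralRecord(
                    referral_date=date,
                    grade=str(row["grade"]),
                    specialty=str(row["specialty"]),
                    urgency=str(row["urgency"]),
                    gcs=int(row["gcs"]),
                    symptom_duration_days=int(row["symptom_duration_days"]),
                    site_id=str(row["site_id"]),
                )
            )
        except (InvalidArgumentError, ValueError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise SchemaError(f"{path}: {len(errors)} invalid row(s): " + "; ".join(errors[:5]))
    return records


def write_series_csv(series: MonthlySeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_series_csv(path, fill_zero: bool = False) -> MonthlySeries:
    df = pd.read_csv(path, dtype={"month": str})
    for col in ("month", "count"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    try:
        months = pd.PeriodIndex(df["month"], freq="M")
    except Exception as exc:
        raise SchemaError(f"{path}: unparseable month column: {exc}")
    counts = pd.to_numeric(df["count"], errors="coerce")
    if counts.isna().any():
        bad = int(counts.isna().idxmax()) + 2
        raise SchemaError(f"{path}: non-numeric count near line {bad}")
    if months.size > 1 and (np.diff(months.asi8) != 1).any():
        if not fill_zero:
            raise SchemaError(
                f"{path}: series has month gaps; pass fill_zero=True to insert "
                "explicit zero-count months"
            )
        full = pd.period_range(months[0], months[-1], freq="M")
        filled = pd.Series(counts.to_numpy(), index=months).reindex(full, fill_value=0)
        logger.warning("%s: filled %d gap month(s) with zero",
                       path, full.size - months.size)
        return MonthlySeries(full, filled.to_numpy())
    return MonthlySeries(months, counts.to_numpy())


def write_forecast_csv(forecast: Forecast, months: pd.PeriodIndex, path) -> None:
    pd.DataFrame(
        {
            "month": months.astype(str),
            "point": forecast.point,
            "lower": forecast.lower,
            "upper": forecast.upper,
            "level": forecast.level,
        }
    ).to_csv(path, index=False)
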