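"""Period-comparison statistics for referral cohorts.

Implements the test battery used to compare referral characteristics across
the pre-pandemic, lockdown, post-lockdown and forecast periods: Pearson
chi-square on contingency tables (no continuity correction), Kruskal-Wallis
with midrank tie correction, Dunn's rank-based post-hoc z tests,
Benjamini-Hochberg step-up false-discovery-rate control, Bartlett's
homogeneity-of-variance test and a Kolmogorov-Smirnov normality check.

The statistics are computed from their closed forms; scipy supplies only
distribution tails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InvalidArgumentError
from .series import MonthlySeries

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeriodDefinition:
    """A named comparison period (closed month window)."""

    name: str
    start_month: str
    end_month: str

    def contains(self, period: pd.Period) -> bool:
        return (pd.Period(self.start_month, freq="M") <= period
                <= pd.Period(self.end_month, freq="M"))


def default_periods() -> list[PeriodDefinition]:
    """Yearly comparison windows around the UK lockdown restrictions."""
    return [
        PeriodDefinition("pre_covid", "2019-03", "2020-02"),
        PeriodDefinition("covid", "2020-03", "2021-02"),
        PeriodDefinition("post_covid", "2021-03", "2021-09"),
        PeriodDefinition("forecast", "2021-10", "2022-09"),
    ]


@dataclass(frozen=True)
class ContingencyTable:
    row_labels: tuple
    column_labels: tuple
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise InvalidArgumentError("counts must be a 2-D matrix")
        if counts.shape != (len(self.row_labels), len(self.column_labels)):
            raise InvalidArgumentError("counts shape must match the labels")
        if np.any(counts < 0):
            raise InvalidArgumentError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(float))


def pearson_chi_square(table) -> dict:
    """Pearson chi-square test of independence (no continuity correction)."""
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(
        table, dtype=float
    )
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise InvalidArgumentError("need at least a 2x2 table")
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    total = counts.sum()
    if np.any(row == 0) or np.any(col == 0) or total == 0:
        raise DegenerateInputError("zero row or column margin: expected counts undefined")
    expected = np.outer(row, col) / total
    statistic = float(np.sum((counts - expected) ** 2 / expected))
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    return {
        "statistic": statistic,
        "df": int(df),
        "p_value": float(stats.chi2.sf(statistic, df)),
    }


def _midranks(pooled: np.ndarray) -> tuple[np.ndarray, float]:
    """Midranks of the pooled sample and the tie-correction sum Σ(t³ − t)."""
    ranks = stats.rankdata(pooled)  # average (mid) ranks
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(tie_counts.astype(float) ** 3 - tie_counts))
    return ranks, tie_sum


def kruskal_wallis(groups: list) -> dict:
    """Kruskal-Wallis H with midrank tie correction; chi-square p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise InvalidArgumentError("need at least 2 non-empty groups")
    pooled = np.concatenate(groups)
    n_total = pooled.size
    if np.ptp(pooled) == 0:
        # all observations identical: no rank variation; H defined as 0
        return {"statistic": 0.0, "df": len(groups) - 1, "p_value": 1.0}
    ranks, tie_sum = _midranks(pooled)
    h = 0.0
    offset = 0
    for g in groups:
        r_g = ranks[offset : offset + g.size].sum()
        h += r_g**2 / g.size
        offset += g.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    correction = 1.0 - tie_sum / (n_total**3 - n_total)
    if correction <= 0:
        raise DegenerateInputError("tie correction degenerate")
    h /= correction
    df = len(groups) - 1
    return {"statistic": float(h), "df": df, "p_value": float(stats.chi2.sf(h, df))}


def dunn_posthoc(groups: list, correction: str = "benjamini_hochberg") -> pd.DataFrame:
    """Dunn's pairwise rank z tests following a Kruskal-Wallis omnibus.

    Returns one row per pair with ``z``, two-sided ``p_raw`` and
    ``p_adjusted`` (Benjamini-Hochberg by default).
    """
    if correction not in ("benjamini_hochberg", "none"):
        raise InvalidArgumentError(f"unknown correction {correction!r}")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise InvalidArgumentError("post-hoc comparisons need at least 3 groups")
    if any(g.size == 0 for g in groups):
        raise InvalidArgumentError("groups must be non-empty")
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks, tie_sum = _midranks(pooled)
    mean_ranks = []
    offset = 0
    for g in groups:
        mean_ranks.append(ranks[offset : offset + g.size].mean())
        offset += g.size
    tie_term = tie_sum / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(base_var * (1.0 / groups[i].size + 1.0 / groups[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_i": i, "group_j": j, "z": float(z), "p_raw": float(p_raw)})
    out = pd.DataFrame(rows)
    if correction == "benjamini_hochberg":
        out["p_adjusted"] = benjamini_hochberg(out["p_raw"].to_numpy())["adjusted"]
    else:
        out["p_adjusted"] = out["p_raw"]
    return out


def benjamini_hochberg(p_values, q: float = 0.05) -> dict:
    """Step-up FDR control; returns rejections at level ``q`` and adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InvalidArgumentError("p_values must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise InvalidArgumentError("q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    thresholds = (np.arange(1, m + 1) / m) * q
    below = ranked <= thresholds
    rejected = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.max(np.nonzero(below)[0]))
        rejected[order[: k + 1]] = True
    adjusted_sorted = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.clip(adjusted_sorted, 0.0, 1.0)
    return {"rejected": rejected, "adjusted": adjusted}


def bartlett(groups: list) -> dict:
    """Bartlett's test of equal variances (chi-square approximation)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise InvalidArgumentError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise InvalidArgumentError("each group needs at least 2 observations")
    variances = [g.var(ddof=1) for g in groups]
    if any(v <= 0 for v in variances):
        raise DegenerateInputError("zero-variance group: Bartlett statistic undefined")
    k = len(groups)
    n_i = np.array([g.size for g in groups], dtype=float)
    n = n_i.sum()
    sp2 = np.sum((n_i - 1) * variances) / (n - k)
    num = (n - k) * np.log(sp2) - np.sum((n_i - 1) * np.log(variances))
    c = 1.0 + (np.sum(1.0 / (n_i - 1)) - 1.0 / (n - k)) / (3.0 * (k - 1))
    statistic = float(num / c)
    return {"statistic": statistic, "p": float(stats.chi2.sf(statistic, k - 1))}


def distribution_checks(sample) -> dict:
    """Kolmogorov-Smirnov distance of the sample against a fitted normal.

    The reference normal uses the sample mean and SD; with estimated
    parameters the test is conservative (no Lilliefors adjustment applied).
    """
    sample = np.asarray(sample, dtype=float)
    if sample.size < 5:
        raise InvalidArgumentError("need at least 5 observations")
    sd = sample.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero-variance sample: normality check undefined")
    stat, p = stats.kstest(sample, "norm", args=(sample.mean(), sd))
    return {
        "ks_statistic": float(stat),
        "ks_normality_p": float(p),
        "note": "reference normal uses estimated mean/SD; p-value is conservative",
    }


GRADE_AGGREGATION = {
    "FY": "intern", "intern": "intern",
    "SHO": "resident", "SpR": "resident", "resident": "resident",
    "consultant": "attending", "attending": "attending",
}


def grade_contingency_table(records, periods: list[PeriodDefinition]) -> ContingencyTable:
    """Grade (intern/resident/attending) by period contingency table.

    Grades outside the three aggregated categories are excluded.
    """
    grades = ("intern", "resident", "attending")
    usable = [p for p in periods if p.name != "forecast"]
    counts = np.zeros((3, len(usable)))
    for rec in records:
        agg = GRADE_AGGREGATION.get(rec.grade)
        if agg is None:
            continue
        month = pd.Period(rec.referral_date, freq="M")
        for j, period in enumerate(usable):
            if period.contains(month):
                counts[grades.index(agg), j] += 1
                break
    return ContingencyTable(
        row_labels=grades,
        column_labels=tuple(p.name for p in usable),
        counts=counts,
    )


def period_summary(records, series: MonthlySeries | None,
                   periods: list[PeriodDefinition] | None = None) -> dict:
    """Per-period descriptive summary plus the omnibus/post-hoc test battery.

    Returns a dict with a ``summary`` DataFrame (one row per period), the
    grade contingency table, and the statistics of the battery: Kruskal-
    Wallis across monthly volumes, Dunn post-hoc (if >= 3 non-empty
    periods), chi-square on the grade table and on urgency proportions.
    """
    periods = periods or default_periods()
    rows = []
    monthly_volume_groups = {}
    for period in periods:
        in_period = [r for r in records
                     if period.contains(pd.Period(r.referral_date, freq="M"))]
        row: dict = {"period": period.name, "n_records": len(in_period)}
        if not in_period and series is None:
            row["missing"] = True
            rows.append(row)
            continue
        row["missing"] = len(in_period) == 0
        if series is not None:
            try:
                sub = series.window(period.start_month, period.end_month)
                vols = sub.counts.astype(float)
                row["median_monthly_volume"] = float(np.median(vols))
                row["volume_iqr_low"], row["volume_iqr_high"] = [
                    float(v) for v in np.percentile(vols, [25, 75])
                ]
                monthly_volume_groups[period.name] = vols
            except InvalidArgumentError:
                pass
        if in_period:
            by_month: dict = {}
            for r in in_period:
                by_month.setdefault(pd.Period(r.referral_date, freq="M"), set()).add(
                    r.site_id
                )
            sites = np.array([len(v) for v in by_month.values()], dtype=float)
            row["median_unique_monthly_sites"] = float(np.median(sites))
            urg = np.array([r.urgency == "urgent" for r in in_period])
            row["urgent_percent"] = float(100.0 * urg.mean())
            row["emergency_percent"] = float(100.0 * (1 - urg.mean()))
            durations = np.array([r.symptom_duration_days for r in in_period], float)
            row["median_symptom_duration"] = float(np.median(durations))
            row["duration_iqr_low"], row["duration_iqr_high"] = [
                float(v) for v in np.percentile(durations, [25, 75])
            ]
            row["median_gcs"] = float(np.median([r.gcs for r in in_period]))
        rows.append(row)

    out: dict = {"summary": pd.DataFrame(rows)}
    groups = [g for g in monthly_volume_groups.values() if g.size > 0]
    if len(groups) >= 2:
        out["volume_kruskal_wallis"] = kruskal_wallis(groups)
        if len(groups) >= 3:
            out["volume_dunn"] = dunn_posthoc(groups)
    table = grade_contingency_table(records, periods)
    out["grade_table"] = table
    if (table.counts.sum(axis=1) > 0).all() and (table.counts.sum(axis=0) > 0).all():
        out["grade_chi_square"] = pearson_chi_square(table)
        # pairwise period chi-squares with BH-corrected p-values
        pair_rows = []
        for i, j in combinations(range(table.counts.shape[1]), 2):
            sub = table.counts[:, [i, j]]
            if (sub.sum(axis=1) > 0).all() and (sub.sum(axis=0) > 0).all():
                res = pearson_chi_square(sub)
                pair_rows.append({
                    "period_i": table.column_labels[i],
                    "period_j": table.column_labels[j],
                    **res,
                })
        if pair_rows:
            pw = pd.DataFrame(pair_rows)
            pw["p_adjusted"] = benjamini_hochberg(pw["p_value"].to_numpy())["adjusted"]
            out["grade_pairwise"] = pw
    return out
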