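# refcast

Forecasting and period-comparison statistics for monthly acute-referral
volumes.

Specialist surgical centres receive emergency referrals (here: acute
pituitary disease — apoplexy, haemorrhage, compressive tumours) through
electronic referral networks.  Planning on-call cover and service expansion
needs two things: a forecast of monthly referral volume, and statistical
comparison of referral characteristics across service periods (before,
during and after the COVID-19 lockdown, and a forecast year).  `refcast`
implements both as a tested, reproducible pipeline, with a synthetic-data
generator standing in for confidential referral records.

## What it computes

**Forecasting.**  The headline model is STL + auto-ARIMA: the count series
`y(t)` is decomposed additively by seasonal-trend decomposition using loess,

    y(t) = s(t) + T(t) + r(t),

the seasonal `s` is extended by repeating its last yearly cycle, and the
trend `T` and remainder `r` are each forecast by an ARIMA(p, d, q) whose
order is selected by an automated grid search minimising
AIC = 2k − 2 log L (exact Gaussian likelihood via a Kalman filter; the
trend's differencing degree is fixed first by unit-root testing).  The
recomposed forecast carries Gaussian intervals with component variances
summed.  Comparators: a random-walk baseline (last value), a
historical-average baseline (training mean), a piecewise-linear-trend +
Fourier additive regression with a declarable lockdown window, and an
adapter socket for external models.

**Evaluation.**  Blocked cross-validation — random (seeded) placement of
disjoint test blocks, each preceded by its own training window, repeated
many times — scored by median absolute error and median absolute
percentage error at 1-, 3-, 6- and 12-month horizons, with paired
sign-flip permutation comparison against the baselines.

**Cohort statistics.**  Pearson chi-square (uncorrected), Kruskal–Wallis,
Dunn post-hoc z-tests, Benjamini–Hochberg FDR control, Bartlett and
Kolmogorov–Smirnov checks, computed from closed forms and organised into a
per-period summary battery.

See `docs/methods.md` for models, assumptions, defaults and limitations.

## Worked example

```python
import numpy as np
from refcast import (SeriesGeneratorConfig, generate_monthly_series,
                     stl_arima_forecast, pearson_chi_square)

# 89 months of synthetic referrals (June 2014 onwards) with growth,
# yearly seasonality and a lockdown dip
series = generate_monthly_series(SeriesGeneratorConfig(seed=11))
fc = stl_arima_forecast(series, horizon=12, grid=(2, 1, 2))
print(np.round(fc.point[:3], 1), "median:", round(float(np.median(fc.point)), 1))

# referrer grade (intern/resident/attending) by period contingency table
grades = [[23, 30, 31], [50, 22, 28], [8, 10, 6]]
res = pearson_chi_square(grades)
print(round(res["statistic"], 1), res["df"], round(res["p_value"], 3))
```

prints

```
[13.4 14.8 14.5] median: 16.0
11.9 4 0.018
```

— the first line is the next three months' point forecasts and the median
forecast monthly volume for the coming year (the series ends near 13–14
referrals/month and the fitted trend continues upward); the second is the
chi-square test of whether the referrer-grade mix changed across periods
(statistic 11.9 on 4 df, p ≈ 0.02: it did, driven by fewer
resident-conveyed referrals from the lockdown period onwards).

The same stages are available from the shell:

```sh
refcast simulate --out demo --seed 11
refcast forecast --in demo/series.csv --horizon 12 --grid 2,1,2 --out demo/forecast.csv
refcast evaluate --in demo/series.csv --models stl_arima,random_walk --reps 100 --seed 7 --out demo/scores.csv
refcast cohort-stats --records demo/records.csv --series demo/series.csv --out demo/summary.csv
refcast run-all --out demo_run --seed 0
```

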