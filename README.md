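# ricetrend

Analysis pipeline for long-term rice yield–climate records: seasonal
climate aggregation with quality control, linear climate trends,
first-difference regression of yield on climate, cultivar-group
summaries, and projected yield changes — plus a synthetic generator of
daily weather and cultivar yields so the whole chain can be exercised
and verified without any external data.

## The problem

Century-scale field trials (the motivating case is the 1925–2019
Pon-Lai rice trials at the Taichung research farm in Taiwan, run over
cool Jan 20–Jun 23 and warm Jul 4–Nov 22 cropping seasons) record both
grain yield and daily weather. Asking "how does yield respond to
climate?" directly on the level series is confounded: yields drift
upward for decades through breeding and management ("technology
trend"). The standard remedy is to regress year-to-year *first
differences*. With seasonal climate summaries T (mean daily average
temperature, °C), DTR (mean diurnal temperature range, °C), R (total
rainfall, mm) and S (total sunshine duration, h), the package fits, per
cultivar and season,

    ΔY = β₀ + β_T ΔT + β_DTR ΔDTR + β_R ΔR + β_S ΔS + ε ,

where Δv(y) = v(y+1) − v(y) over consecutive trial years only (pairs
never span an experiment gap). Any linear-in-year technology term
differences into a constant absorbed by β₀, leaving the climate
coefficients untouched. Coefficients are normalised into percent form
β% = 100·β / (average grain yield) so cultivars with different yield
levels are comparable.

Each climate variable's own history is summarised by an OLS time trend
x = β₀ + β₁t + ε; the trend-implied total change of a period
[start, end] is β₁·(end − start). Combining the two fits gives, per
cultivar, variable and period:

* total relative yield change (%) = β% × ΔClimate_total
* annual actual yield change (kg·ha⁻¹·yr⁻¹) = β × ΔClimate_total / n_years

with n_years = end − start + 1. Cultivars with overlapping cultivation
periods are grouped, and group values are member means ± SD.

## Worked example

```python
from ricetrend import (FirstDifferenceYieldModel, fit_linear_trend,
                       trend_total_change)
from ricetrend.simulate import WeatherScenario, synth_weather
from ricetrend.weather import impute, aggregate_seasons

wx = synth_weather(WeatherScenario(seed=42))   # 95-year daily record
clean, report = impute(wx)                     # neighbor-year imputation
seasonal = aggregate_seasons(clean, report=report)

cool = seasonal[seasonal.season == "cool"]
fit = fit_linear_trend(zip(cool["year"], cool["T"]), variable="T",
                       season="cool")
print(fit.summary())
print(trend_total_change(fit, 1925, 2019).delta_total)
```

prints

```
T (cool): slope +0.009631/yr**  intercept 2.973  r2=0.287  n=95  p=2.22e-08
0.905…
```

— the cool-season mean temperature warms by ≈0.91 °C over the 94-year
span (`**` marks p < 0.01), close to the generator's ground-truth
(trend_tmin + trend_tmax)/2 × 94 = 0.89 °C. Fitting a cultivar whose
yields were generated with β_T = 100, β_DTR = −60, β_R = −0.6,
β_S = 1.5 and 200 kg/ha noise:

```
First-difference regression: DEMO (cool)
n_pairs=89  r2=0.594  avg yield=6117.1 kg/ha
  term  beta (kg/ha/unit)         se  pct (%/unit)
 const            15.0506    25.7945
     T           141.8660    49.5625        2.3192
   DTR           -60.7052    34.4466       -0.9924
     R            -0.5533     0.1935       -0.0090
     S             1.6532     0.3648        0.0270
```

Every recovered coefficient sits within one standard error of its
ground truth; the 15 kg/ha/yr technology trend re-appears as the
intercept of the differenced model, exactly as the method intends.

## Command line

```sh
ricetrend simulate --seed 1 --out inputs/     # synthetic weather + yields + config
ricetrend run --config inputs/config.yaml --out run/
ricetrend report --from run/                  # rounded tables
```

`run` writes `seasonal_climate.csv`, `climate_trends.csv`,
`regression_results.csv`, `group_summary.csv`, `correlations.csv`,
`yield_changes.csv`, a QC log and a manifest; reruns on identical
inputs are bit-identical.

Input dialects: weather CSV `date,tavg,tmin,tmax,rain,sunshine`
(ISO dates, empty field = missing) and yield CSV
`cultivar,season,year,yield` (kg/ha; years with no experiment are
absent rows, never zeros).

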