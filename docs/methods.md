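# Methods

## Model and procedure

The pipeline estimates the climate sensitivity of rice grain yield from
a long-term two-season field trial and its co-located weather station.
It runs in five stages.

**1. Weather quality control.** Daily records carry average, minimum
and maximum temperature (°C), rainfall (mm) and sunshine duration (h).
A cell is flagged when it is absent, or when it deviates from its
day-of-year climatology (mean over a ±7-day circular window across all
years) by more than `outlier_z` standard deviations (default 4). A
flagged cell on calendar day (m, d) of year y is replaced by the mean
of the same calendar day in years y−1 and y+1; at the ends of the
record the single available neighbor is used. Cells whose neighbors are
themselves flagged are retried in later passes using already-imputed
values; a cell that never resolves stays absent and aggregation over
any window containing it raises an error naming the day. Feb 29
neighbor lookups fall back to Feb 28 in non-leap years, since the same
calendar day does not exist there. Every replacement is logged with
date, variable, old value, new value and rule.

*Assumptions and caveats.* The neighbor-year rule is the convention of
the station record this package targets; it preserves sample size but
biases variances slightly downward. Rainfall is zero-inflated and
heavy-tailed, so the same z-rule trims genuinely extreme wet days more
often than temperature spikes; rain replacements are identifiable in
the log by their variable. Imputation is exactly idempotent on the
missing-value path; a borderline outlier lying within numerical noise
of the z-threshold can, in principle, flip between successive runs
because replacements shift the climatology.

**2. Seasonal aggregation.** Fixed date-anchored windows — cool
Jan 20–Jun 23, warm Jul 4–Nov 22 by default — are reduced per year to
T = mean(tavg), DTR = mean(tmax − tmin), R = Σ rain, S = Σ sunshine,
endpoints inclusive. Feb 29 lies inside the cool window, so `n_days` is
156 in leap years and 155 otherwise. The record also carries the count
of imputed days inside the window.

**3. Climate trends.** Each seasonal series is fitted by OLS against
calendar year as-is (no centering; the intercept is never interpreted).
The slope's two-sided p-value uses the t-distribution with n−2 degrees
of freedom, and significance is displayed as `**` (p < 0.01), `*`
(0.01 ≤ p < 0.05), `’` (0.05 ≤ p < 0.1), with boundary values assigned
to the weaker class as a deterministic tie rule. The trend-implied
total change over [start, end] is slope × (end − start) — the rise of
the regression line between the endpoint years, not the count of years.

**4. First-difference regression.** Per cultivar and season, yield and
climate series are differenced over consecutive calendar years both
present; pairs never bridge an experiment gap, because differencing
across a multi-year gap would reintroduce the technology change the
transform exists to remove. The five-parameter OLS (intercept + four
climate anomalies) requires at least `min_pairs` (default 6) rows and a
full-rank design; rank deficiency raises an error naming the implicated
columns via the design's null space. Percent coefficients are
100·β / (average grain yield over all present years). The absolute β
is the stored source of truth; the ×100 is applied at reporting and can
be disabled (`percent_times_100`).

**5. Grouping and projection.** Cultivars are grouped either from an
explicit configuration (reproducing the published membership, including
the two-member 1977–1983 group which is computed, written, and flagged
`excluded`) or as connected components of the interval-overlap graph.
Group summaries are member means with sample SD (ddof = 1; undefined
for a single member). Pearson correlations are computed on
pairwise-complete first-difference series (a levels option exists for
yield pairs); pairs with fewer than 3 complete observations are left
undefined with a log entry. Projections per group, variable and period
combine each member's coefficient with the period's trend-implied
climate change: total relative change = β% × ΔClimate, annual actual
change = β × ΔClimate / n_years with n_years = end − start + 1 (20, 39
and 24 for the standard periods). At the member level the two satisfy
annual = (total/100) × average yield / n_years identically. ΔClimate
defaults to a trend *refitted inside the period* (`delta_mode:
period-local`); a `global` mode applies the full-record slope over the
period span instead. Both are defensible readings of a per-interval
analysis; the manifest records which was used. Group projections
average member-level estimates; excluded groups are omitted from the
projection table.

## Synthetic data generator

`WeatherScenario` emulates a 95-year subtropical lowland station
record: a sinusoidal annual temperature cycle (coldest mid-January)
with AR(1) daily anomalies plus a year-level anomaly; linear warming
concentrated in the minimum temperature (defaults 0.016 °C/yr for tmin
vs 0.003 °C/yr for tmax, i.e. ≈0.9 °C total mean warming and a
declining DTR over 94 years); Bernoulli–Gamma daily rainfall whose
Gamma scale drifts to produce a prescribed annual-total trend and is
modulated by a mean-one lognormal yearly wetness factor; sunshine
proportional to day length, reduced on wet days and in wet years (the
same wetness draw with opposite sign, producing the negative rain–
sunshine correlation characteristic of station data), with its own
declining trend; and a fraction of wholly missing days (default 2.65 %,
flagged as empty, never zero). Defaults were chosen once to match the
first moments, trend signs and approximate magnitudes of the 1925–2019
Taichung record (cool/warm season means ≈22/26 °C, DTR ≈8.6 °C,
seasonal rainfall several hundred mm, ≈0.9–1 °C total warming).

What it deliberately does not reproduce: typhoon-scale rainfall
extremes and their interannual clustering (seasonal rainfall SD is
roughly half the real record's), the real record's higher warm-season
sunshine, day-to-day weather regimes beyond AR(1), and the 1984 station
relocation (the record is generated as one homogeneous series, which is
also how the analysis treats the real one). Passing tests therefore
demonstrate correctness of the *estimators* under a known data-
generating process, not that the real record satisfies the model's
assumptions.

`YieldScenario` inverts the regression model exactly: yearly yield =
intercept + technology trend × (year − first year) + β·(T, DTR, R, S) +
Gaussian noise, with experiment gap years absent. Because the generator
and the estimator share the model only through the *levels* data, the
recovery tests are a genuine round trip: differencing, gap handling and
joining are all exercised.

## Numerical choices

* OLS is delegated to `scipy.stats.linregress` (trend) and
  `statsmodels` OLS (multiple regression); tests check both against
  independently coded closed-form and normal-equations oracles to 1e-8
  or better.
* r² is clamped to [0, 1]; a zero-variance response is reported as
  r² = 1 for a perfect fit and 0 otherwise, with p = 1.
* Degenerate inputs raise typed errors: fewer than 3 trend points or
  `min_pairs` difference rows (insufficient data), identical years or a
  collinear design (rank), a season window with an unresolved missing
  day (aggregation, naming the day), invalid scenario parameters
  (configuration).
* Seeds: every stochastic component runs off `numpy.random.default_rng`
  seeded from the scenario; identical scenario + seed is byte-identical
  through every stage including written CSVs.
* Test and acceptance problem sizes — 8–12-year toys for exactness
  checks, a 90-year span with 50 replicates for the recovery study —
  were chosen as the smallest sizes at which the respective properties
  are informative (a 5-parameter fit needs ≥6 pairs; Monte-Carlo means
  need ~50 replicates for a stable standard error).

## Known limitations

* The percent normalisation divides by a cultivar's mean yield over its
  whole span; for cultivars grown across decades this mixes early and
  late technology levels into the denominator.
* Plain OLS standard errors throughout; no autocorrelation-robust
  (Newey–West) correction, matching the analysis this package
  implements.
* No break-point homogenisation for station relocations; the series is
  treated as continuous.
* The interval-overlap grouping is purely temporal; no yield-similarity
  clustering.
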