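# Methods

## The question the package operationalizes

An air-quality index is useful as a *risk communication* tool only if the
daily index value tracks the population health risk of the day's air.
The package evaluates two index constructions against daily respiratory
emergency-department (ED) counts:

1. **AQI** — regulatory, single-pollutant: per pollutant, the
   concentration (truncated to its reporting precision) is mapped through
   piecewise-linear breakpoint segments
   `I = (I_hi − I_lo)/(C_hi − C_lo)·(C − C_lo) + I_lo`, rounded to the
   nearest integer (half away from zero); the daily AQI is the maximum
   sub-index, and the arg-max pollutant is reported as responsible.
   Ties are broken by the fixed priority PM2.5 > O3 > NO2 — ties are
   measure-zero in real data, but a deterministic rule keeps outputs
   reproducible. Concentrations above the top breakpoint clamp to the
   top index with a logged warning; guidance for off-scale values is
   ambiguous and they never occur in the intended operating range.
   Breakpoints live in a versioned CSV (default: the table in force
   2012–2014 for 24-h PM2.5, 8-h O3, 1-h NO2); they have since been
   revised, so other periods should load their own file.

2. **Health-based index** — additive excess risk in the AQHI style:
   `index = s · Σ_p 100·(exp(β_p x_p) − 1)` with `β_p` a pooled log-RR
   per concentration unit. The scale constant `s` is analysis-neutral
   (associations per IQR are invariant to it, which the test suite checks
   to 1e-12); default is the raw excess-risk sum, with
   `calibrate_scaling` available to map a reference quantile (default
   99th) onto a banded presentation scale. Coefficients are an *input
   file* with a units column checked against the series units; the
   shipped `health_coefficients_synthetic.csv` is a synthetic example
   with plausible magnitudes for tests and illustration — it is not a
   canonical literature meta-analysis.

## Random-effects pooling

Both the literature coefficients and the county associations are pooled
with the DerSimonian–Laird estimator: fixed weights `w_i = 1/se_i²`,
Cochran's `Q`, `τ² = max(0, (Q−(k−1))/(Σw − Σw²/Σw))`, random-effects
weights `1/(se_i²+τ²)`. When `Q ≤ k−1` this reduces exactly to
fixed-effect inverse-variance pooling; a single estimate passes through
with `τ² = 0` and a logged note. `I² = max(0, (Q−(k−1))/Q)`.
Confidence intervals use `z = 1.959964` throughout; no small-sample
adjustment is applied.

## The count model

Daily counts are modelled by a log-link Poisson GLM with quasi-likelihood
dispersion:

```
log E[Y_t] = β0 + β_x · x_t(lag) + dow_t + ns(t; df_trend)
           + ns(temp_t; df_T) + ns(mean(temp_{t−1..t−3}); df_LT)
           + ns(rh_t; df_RH)
```

- **Exposure** `x_t` is a pollutant column or a daily index series. The
  primary lag metric is the 4-day trailing moving average of lags 0–3;
  single-day lags d ∈ 0..5 are the degenerate window (d, d). Lags are
  computed on the *full* calendar series before the season subset is
  taken, so early-season rows keep valid lags; the series is re-indexed
  to a gap-free daily calendar first (gap days become missing and are
  dropped, with the count reported).
- **Seasons**: cool = November–February (blocks labelled by the year of
  their November), warm = March–October. Trend/seasonality is a natural
  cubic spline on the sequential within-season day index with
  df = (df per season-year) × (number of season-year blocks); defaults
  are 8/season-year in the cool season and 16 in the warm season.
  Full-year fits (`season="all"`) use 12 df per calendar year, a
  conventional choice for year-round daily time series.
- **Day of week** enters parametrically; the default coding is six
  indicator columns (Monday reference), which nests the optional literal
  linear (0–6) coding.
- **Weather splines** default to AIC selection over the candidate grid
  {2, 3, 4, 5}: a joint grid search over exactly the terms marked
  `"aic"`, minimizing `AIC = 2p − 2ℓ` with the Poisson log-likelihood
  evaluated at the quasi-Poisson estimates, ties toward the smaller
  total df. A QAIC variant (`2p − 2ℓ/φ̂`) is available but not default.

**Natural splines.** The basis spans the same space as R's
`splines::ns`: df columns, interior knots at equally spaced quantiles,
boundary knots at the data min/max, linear beyond the boundaries. It is
built from the truncated-power natural basis on the unit interval;
inside the design matrix each spline block is QR-orthonormalized, which
leaves the spanned adjustment space (and hence the exposure estimate)
unchanged while keeping the design well conditioned even with 30+ trend
columns. Knots at quantiles rather than equal spacing is the standard
choice in this literature and is robust to skewed covariates.

**Fitting.** IRLS with deterministic initialization (constant linear
predictor at `log(mean y)`), relative deviance tolerance 1e-9, maximum
100 iterations, plus one extra Newton refinement step after the stopping
rule fires (IRLS is Newton-like, so the extra step pushes the estimate
to machine-precision MLE; this is what makes the exposure-rescaling
invariance hold to 1e-12). Point estimates equal the ordinary Poisson
MLE; the covariance is the inverse Fisher information — computed via QR
of the weighted design rather than by inverting X'WX, again for
conditioning — scaled by the Pearson dispersion `φ = X²/(n−p)`, so
quasi standard errors are exactly Poisson standard errors × √φ. Rank
deficiency is detected by pivoted QR and reported with the names of the
collinear columns; non-convergence raises with the deviance trace.

**Effect scale.** Associations are reported as RR per IQR:
`RR = exp(β̂·IQR)`, CI `exp((β̂ ± 1.959964·se)·IQR)`. The IQR is taken
over the analysis-ready lagged exposure within the county-season being
fit (matching per-county estimation); a common region-level IQR can be
supplied for cross-county comparability. County log-RRs are pooled on
the per-IQR log scale with county-specific IQRs by default.

**Model validation.** The observed-vs-fitted adjusted R² diagnostic is
the adjusted R² of the least-squares regression of observed counts on
fitted means, with the model's parameter count in the adjustment; it is
reported per fit alongside φ, n used and the AIC.

## Monitor aggregation

Counties with several monitors are combined per pollutant: within each
season × season-year block, monitors reporting fewer than 75% of the
block's days are dropped for that block (applying the filter per block
rather than per pooled season is the stricter reading; either passes the
same contract tests), and the remaining monitors are combined per day as
both the cross-monitor mean (analysis default) and maximum.

## The synthetic-data generator

Real inputs of this design — restricted ED records, regulatory monitor
downloads — cannot ship with a package, so the generator produces
multi-county series with the structure the analysis assumes and a known
truth to recover:

- **Pollutants**: annual sinusoid (mean, amplitude, peak day) plus AR(1)
  noise parameterized by its stationary sd, truncated at 0.
  Cross-pollutant dependence comes from a Gaussian copula on the
  innovations, with target Spearman correlations converted to Pearson
  via `r = 2 sin(πρ_s/6)`; a non-positive-semi-definite target is
  rejected with the offending eigenvalues. Note the copula governs the
  *innovation* dependence: shared seasonal cycles add rank correlation
  on top, so the realized-correlation contract is tested with
  amplitudes at zero.
- **Weather**: same construction for temperature and relative humidity,
  RH clipped to [0, 100].
- **Counts**: the log-mean contains a winter-peaking seasonal sinusoid
  (amplitude 0.2 on the log scale by default), an optional linear trend,
  day-of-week factors, small linear weather terms, and
  `Σ_p β_p · MA4(pollutant_p)` with
  `β_p = log(true RR per IQR)/IQR_p` computed from the *realized* IQR of
  the lagged exposure — so "true RR per IQR" is exact by construction.
  The linear predictor is centred so the mean expected count equals the
  configured baseline exactly. Overdispersion is a gamma-mixed Poisson
  (negative binomial with variance = φ·mean, the same second-moment
  contract quasi-likelihood assumes); φ = 1 draws pure Poisson. The
  default φ = 1.3 is a free choice — realized dispersion of real ED
  series is rarely reported — and is exposed in the config.
- A burn-in of max(lag, 3) days precedes the requested start date so
  every output day has fully defined lagged exposure and lag-1..3
  temperature.
- Counties are independent substreams of one seed
  (`default_rng([seed, county_index])`); identical config + seed is
  bitwise reproducible.

Default magnitudes (PM2.5 ~11 µg/m³ winter-peaking, O3 ~45 ppb
summer-peaking, NO2 ~25 ppb winter-peaking, modest cross-correlations)
put medians, IQRs and correlations in the ranges typical of the
California regions this design emulates. What the generator does *not*
emulate: multi-modal seasonality, spatially resolved exposure error,
monitor network structure, holiday effects, epidemic outbreaks in the
counts. Passing recovery tests therefore demonstrate internal
consistency of generator + estimator, not robustness to every feature of
real surveillance data.

## Calibration studies (`aqindex.validation`)

- **Parameter recovery**: 300 independent simulated counties, 3 years of
  daily data each, baseline 100 visits/day, true RR 1.03 per IQR on
  4-day-MA PM2.5, φ = 1.3. Each county is fit with the full-year model
  (trend 12 df/year, weather splines at 3 df) so that the IQR used for
  standardization coincides with the one truth was injected on; the
  quasi-scaled 95% CI should cover the injected truth ~95% of the time
  and the point estimates should average to the truth. The replicate
  count and problem size keep the full study under a minute on one core.
- **Null calibration**: 500 replicates at true RR 1.0; the nominal
  two-sided 5% test should reject ~5% of the time.

## Degenerate inputs and numerical conventions

- All-missing pollutant day → missing AQI (never zero); any missing
  pollutant → missing health-index value.
- Missing values propagate through lag windows; rows with any missing
  covariate are dropped and counted (on a gap-free series with the 0–3
  window, exactly 3 rows drop).
- Constant variables yield missing Spearman cells; fewer than 3 pairs
  likewise. Ties use mid-ranks.
- Spline construction requires at least df+1 distinct values and names
  the offending variable otherwise.
- CSV interchange uses ISO-8601 dates, empty fields for missing values,
  and round-trip float formatting (`%.17g` out, `float_precision=
  "round_trip"` in), so write-then-read is exact.

## Known limitations

- The AQI engine recomputes the index from the three study pollutants
  only; an agency-reported AQI could occasionally be driven by CO, SO2
  or PM10, which are outside this analysis's series (the breakpoint file
  format accepts additional pollutants).
- DerSimonian–Laird is the classical moment estimator; it is known to
  understate uncertainty when k is small and heterogeneity is large.
  No Knapp–Hartung adjustment is applied.
- AIC selection of weather-spline df is per fit (per county-season) by
  default; fixing df globally is supported by passing integers.
- The demographic tables use a fixed category dictionary (ages 18–40 /
  41–64 / 65+, sex, six race/ethnicity groups); unknown categories are
  folded into "other" with a warning.
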