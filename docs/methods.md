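# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `hatchclim`. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Nest metrics

A clutch is summarised at excavation by four counts: empty shells *S*
(eggs that hatched; shell-fragment adjudication — only shells with more
than half remaining counted — happens in the field and is upstream of this
package), unhatched eggs *U*, and live/dead hatchlings *L*, *D* found in
the nest. Hatching success H = S/(S+U) is undefined when S+U = 0, and
emergence rate R = (S−(L+D))/S when S = 0. Undefined values propagate as
missing and are excluded from the affected stratum mean only — never
coerced to zero, which would bias monthly means downward in bad seasons
exactly when the clutch-level denominator vanishes. The record type
enforces the count identities (all counts ≥ 0, L + D ≤ S) at construction,
so H, R ∈ [0, 1] whenever defined. Lay months outside October–January are
rejected at parse time with a warning (February clutches are too few to
analyse). Stratum means sort values before averaging so the result is
exactly invariant to record order.

Annual values weight the four lay-month values by the long-run temporal
distribution of nesting, (0.13, 0.27, 0.35, 0.25) for Oct–Jan. The printed
weights sum to 1.00 and are treated as exact. If a month is missing its
weight is redistributed proportionally over the remaining months, with a
logged warning.

Reported cohort percentages use round-half-away-from-zero to integers.
Variance shares of standardized coefficients use largest-remainder
rounding so the shares always sum to exactly 100.

## Regressions

Predictor selection is forward stepwise with backward elimination on
partial t-test p-values, alpha_enter = alpha_remove = 0.05 — the era's
default practice for this kind of analysis; selection operates on raw
(unstandardized) predictors. Non-finite p-values (exact fits with zero
residual variance) never trigger entry. If nothing enters, an
intercept-only fit is returned with a warning rather than an error, so
pipelines degrade visibly instead of dying. Perfectly collinear candidates
raise an error naming the dependent columns. Standardization uses sample
standard deviations (n−1 denominator): β_j = b_j · sd(x_j)/sd(y).

The packaged reference models (hatching success on prior-two-month
precipitation, October precipitation and incubation temperature; emergence
rate on incubation temperature and September–October precipitation) store
*effective additive* coefficients: the temperature coefficients are
negative (−6.06×10⁻² and −0.14) and all precipitation coefficients
positive. This sign convention is the only one that yields predictions on
the unit interval at realistic inputs (~27 °C, hundreds of mm) and matches
the biology — warm, dry incubations are unfavourable. Predictions are
clamped to [0, 1] because the responses are proportions; clamping events
are counted and logged so heavy clamping is visible rather than silent.

The candidate set for refitting deserves a note. Several precipitation
accumulation windows (one, two and three months before laying, the
incubation months, the rainy-season total) are plausible predictors and are
all available via `predictor_table(extended=True)` for audit; however the
1-, 2- and 3-month windows are correlated above 0.9, so a stepwise run over
the full window list selects among them essentially arbitrarily. The
default candidate sets used by `hatchclim fit` are therefore the reference
models' own predictors plus one decoy window (incubation-period
precipitation) to keep selection honest without making "which window" a
coin flip.

## Hindcast calendar

"Two months of incubation" means the lay month and the following month
(incubation lasts about 60 days); "two months before eggs were laid" means
the two full calendar months preceding the lay month. A season labelled Y
runs October Y – February Y+1, so January clutches of season Y use
November/December of Y as their prior window and January/February of Y+1
as their incubation window; October clutches reach back to August and
September of Y. The hindcast span "1976 to 2010" is the 34 seasons 1976–77
through 2009–10. Every predictor is a pure function of (season, lay month)
and the weather table; the tests check all four lay months against an
independently hand-resolved calendar.

## Bias correction

For each calendar month m and variable, factor_m = mean(observed) /
mean(model) over the 1976–2000 reference years, and every model value of
that month is multiplied by factor_m. Two consequences are exact algebra
and are asserted to 1e-10 relative in the tests: corrected reference-period
monthly means equal the observed means, and ratios between any two periods
(trends in relative terms) are preserved. The ratio form is applied to
temperature as well as precipitation by default. Note the caveat: a
multiplicative correction on °C depends on the temperature unit (the same
bias in K would give a different factor); the conventional additive offset
correction for temperature is available via `temp_mode="additive"` and
conserves reference means equally well. The ratio is the default because it
is the stated method of the analysis this package implements.

A model whose reference-period mean precipitation is zero in some calendar
month cannot be ratio-corrected and raises an error rather than producing
infinities.

## Projection summaries

The projection span is the 99 seasons 2001–02 through 2099–2100. Moving
averages are 10-season *trailing* windows (the first nine seasons are
emitted as missing): with a trailing window the 2100 endpoint summarises
only realised seasons. Centred alignment would shift, not change, the
reported trends. Ensemble means are unweighted over members sharing the
season axis exactly; the ENSO-skillful sub-ensemble is selected by an
explicit id list in the configuration, since skill selection comes from
external analysis, not a computable rule. Trend statistics are Pearson
correlations of the (smoothed) series against season index with two-sided
p-values.

## Synthetic data

The generator emulates, for a Guanacaste-like seasonally dry Pacific coast
station, the statistical structure the analysis assumes; it makes no claim
to reproduce any particular station's actual record.

* **ENSO index.** A stationary AR(1) process with coefficient 0.5
  (multi-season persistence) and unit innovation sd, initialised from its
  stationary distribution; one September–October value per season.
  Positive = El Niño.
* **Station weather.** Monthly climatology (defaults: rains May–November
  peaking at ~380 mm in September–October, near-rainless December–April;
  air temperature 26.5–28.7 °C, warmest late in the dry season) plus an
  ENSO response plus Gaussian noise, precipitation truncated at zero. The
  precipitation response and noise are shaped by each month's share of the
  wettest month's climatology: ENSO modulates the rainy season, and a
  uniform additive response would instead flood the dry season in strong
  La Niña years. Defaults (−100 mm and 200 mm noise at the wettest month
  per index unit; +0.5 °C per index unit and 1.0 °C monthly noise) are set
  so the interannual spread matches the documented regime — October
  rainfall ranging from roughly 100 mm in strong El Niño to 600–800 mm in
  strong La Niña seasons — and are applied season-constant (one index
  value forces May Y – April Y+1), matching the use of a single Sep–Oct
  index per season.
* **Nests.** Expected H and R per (season, lay month) come from the
  reference equations on that month's predictors, clamped to [0, 1]. Nest
  level overdispersion is Gaussian jitter (sd 0.12) on the expected
  proportion, clamped, followed by binomial draws: S ~ Bin(clutch, H′)
  with clutch ~ Poisson(65), emerged ~ Bin(S, R′); non-emerged hatchlings
  split 60/40 dead/live. This is the simplest noise model consistent with
  annual SDs of the order 0.2–0.25; the true within-month variance
  structure of real excavation data is unknown, and alternatives
  (beta-binomial) would be equally defensible. A clutch with S = 0 is
  retained with its emergence rate undefined.
* **Model ensemble.** Each member shares the station climatology plus a
  constant temperature offset (±1.5 °C) and multiplicative precipitation
  factor (0.7–1.3) — the injected bias the correction step must remove — a
  linear warming trend (all members; 1.5–4.5 °C/century around the 3 °C
  default) and a drying trend for a configurable majority (default 13 of
  17; the remainder get a weak wetting trend), both active over the full
  1976–2100 span, plus the member's own AR(1) ENSO variability and monthly
  noise.

Every generator seeds `numpy.random.default_rng` with (config seed,
stream id), so outputs are bit-reproducible and independent of call order.

What passing tests on these data do **not** show: that the fitted
regression transfers to any real beach; that real model ensembles have
multiplicative, month-constant biases; or that real sub-monthly weather
effects (which the monthly predictors cannot see) are negligible.

## Simulation-study operating characteristics

Two simulation studies characterise the stepwise machinery at the study's
scale (six seasons, n = 24, 200 replicates; sizes chosen to estimate rates
to ~±3 percentage points):

* **Type-I control.** With a pure-noise response, each candidate is
  retained in ≈5% of replicates, consistent with alpha_enter = 0.05.
* **Parameter recovery.** Data simulated from the reference
  hatching-success equation with noise tuned to R² ≈ 0.8. Plain OLS on the
  generating predictors recovers each coefficient within 2 SE in ≈94% of
  replicates. Joint stepwise retention of all three predictors, however,
  sits near 65–70%, not higher: the printed standard errors of the
  reference equation themselves imply a temperature partial t of about
  2.2 (≈55–60% power at p = 0.05), and with only six AR(1) seasons some
  replicate designs are ENSO-quiet, which depresses the precipitation
  terms' partial signals. Joint retention well above 80% would require
  climate variability stronger than the documented regime, so the
  package reports the honest rate instead.

## Known limitations

* The reference coefficients are taken as given; the underlying six-season
  excavation data are not public, so refits can only be validated against
  synthetic data.
* OLS with stepwise selection ignores the autocorrelation of seasons and
  the shared October predictor across months of a season; no mixed-effects
  or autocorrelation-robust inference is provided.
* The ratio bias correction on temperature is unit-dependent (see above).
* Monthly climate predictors cannot resolve sub-monthly events (storm
  timing, heat spikes near emergence) that are known to matter.
* The emergence observation window ("within two nights of first
  emergence") is treated as final; L and D are taken as excavation truth.
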