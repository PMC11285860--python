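# Methods

`passflow` re-implements, as a tested pipeline, the quantitative analysis of
diurnal insect migration through a mountain-pass bottleneck: a narrow (30 m)
high-mountain pass concentrates southbound autumn migrants so that the whole
assemblage can be counted at ground level from a bidirectional intercept
trap, short video transects and visual counts. This note records the models,
the parameter choices and their rationale, what the synthetic-data generator
does and does not emulate, and the numerical decisions.

## Data model

Four tab-separated tables flow through the pipeline (schemas in
`passflow.io`): daily bidirectional **trap** catches (taxon, direction,
count), 1-min **video** counts of a 2 m strip every 15 min (09:00–17:00, 32
bins per day), 15-min **visual** counts of the full 30 m pass every 2 h, and
daily **weather** (mean temperature °C, wind heading in meteorological
"from" degrees, precipitation mm, windspeed m s⁻¹, sunshine minutes).
Timestamps label bin starts; bins are half-open `[start, start+duration)`.
Validation is strict and total: downstream code never sees a record that
violates an invariant.

## Migrant classification

For each taxon and wind category (headwind/tailwind, from the sign of the
headwind index with a configurable dead-band) the *southward score* is

    score = 100 · (n_south − n_north) / (n_south + n_north),

defined only when at least `min_group_n = 100` individuals were caught in
that category. Categories, in fixed precedence:

1. **HighAltitude** — headwind score ≥ 90 and tailwind n < 100. These taxa
   fight headwinds through the pass but overfly the ridge when winds assist.
2. **FBL** — both scores defined and tailwind score ≥ 50 (directed
   flight-boundary-layer movement regardless of wind). A defined tailwind
   score is required because the literal "headwind score ≤ 100" condition is
   vacuous.
3. **NonMigratory** — at least 100 individuals overall, matching neither
   rule.
4. **Unclassified** — too few individuals to analyse.

All seasons are pooled before scoring (a per-season flag exists); the
field protocol pooled years the same way.

## Bioflow scaling

* Visual counts: ×8 (15 min of each 2-h block observed).
* Video counts: ×15 (time) ×15 (width) = ×225 to the 15-min, 30-m pass.
* Missed-insect correction: 57% of migratory individuals are below the
  camera's ~8 mm resolution limit, so video-derived totals are divided by
  1 − 0.57 = 0.43. The correction inverts a binomial thinning and is
  unbiased; it applies to video counts only (visual counts resolve all
  butterflies/dragonflies, so they receive none).
* MTR (migratory traffic rate) = count / (duration_min · width_m),
  individuals m⁻¹ min⁻¹, comparable across protocols and sites.
* Scaled values stay real-valued internally and are rounded only at report
  time (fold variation to 1 dp) to avoid compounding rounding error.

Biomass prices the pass-level total at the mean per-individual mass implied
by the identified catch composition against a per-taxon mass table
(placeholder masses ship with the default profiles; real analyses supply
their own table). Nitrogen and phosphorus fluxes default to 10% and 1% of
fresh biomass — the ratios implied by the published 140 kg → 14 kg N →
1.4 kg P triple; both are configurable.

## Mass-migration days and diurnal timing

Days are ranked by integrated daily total (video-scaled, missed-corrected,
plus visual-scaled; a flag switches to raw video) and the shortest
descending prefix whose cumulative sum reaches 95% of the grand total is
selected; the crossing day is included, and ties in the total break by
earlier date. The diurnal profile is the mean of each 15-min video bin over
the selected days; its argmax (earliest bin on ties) is the daily peak.

## Weather model

Daily totals are modelled as a zero-inflated negative binomial. A day is a
structural zero with probability π = F(z'γ) where F is the inverse cauchit
link `F(η) = 1/2 + arctan(η)/π` — heavier-tailed than the logistic, which
suits the abrupt all-or-nothing character of migration days; otherwise the
count is NB2 with mean μ = exp(x'β) and dispersion θ (Var = μ + μ²/θ).

Covariates: headwind index `h = cos(heading − headwind_bearing)` with the
full-headwind bearing defaulting to 225° (a wind *from* the southwest
opposes southwest-bound flight), giving the documented −1 (full tailwind)
… +1 (full headwind) range; sunshine proportion `s = sunshine_min / 480`
(the 09:00–17:00 observation window; configurable to daylight length);
rainfall, temperature and windspeed enter untransformed. Candidate
interactions: headwind×windspeed, sunshine×temperature, sunshine×rainfall.

**Fitting.** The likelihood is maximized over (β, γ, log θ) by L-BFGS-B
from deterministic starts (log-linear least squares for β; the inverse link
of the observed zero fraction for the γ intercept) over a small multi-start
grid in the dispersion scale and zero-part intercept, followed by
alternating simplex/quasi-Newton polishing; convergence is certified by a
simplex probe that fails to improve the optimum by more than 10⁻⁶.
Standard errors come from the inverse numerical Hessian (observed
information) at the optimum; z and p values are Wald, unadjusted for
multiplicity, matching standard practice for this model family. A logit
zero link is available and is used in the test suite to cross-check the
fitter against an independent reference implementation.

**Model search.** All-subsets AIC enumeration treats the count and zero
term sets separately (every pair of admissible subsets is fitted;
interactions require both parents when marginality is on; an enumeration
cap guards runtime). Variable importance averages each candidate's AIC over
all subsets of a fixed size containing it — with 7 candidates and size-3
subsets each term appears in C(6,2) = 15 models — with any listed
interaction added when both parents are present. The subset enters the
count part with an intercept-only zero part by default (a mirror flag adds
it to both); the choice is documented rather than inferred because the
importance pool is ambiguous in the source protocol.

**Uncertainty.** Prediction curves (expected count (1−π)·μ along one
covariate, others at their medians) get 95% percentile bands from a
day-resampling bootstrap (B = 999 by default); a warning is attached when
more than 20% of refits fail.

## Fine-scale sunlight analyses

15-min video occasions labelled sun-present/absent are compared by the fold
difference of raw class means and a two-sample t statistic, computed
shade-minus-sun so a positive sun effect yields negative t. The default is
Welch (unequal variance) on log1p counts — counts with order-of-magnitude
fold differences are heteroskedastic and right-skewed — with both the
transform and the variance assumption configurable, since the original
protocol states neither. Visual counts with a 0–100% sun score are fitted
by OLS; F = R²(n−2)/(1−R²) with (1, n−2) df holds exactly.

## Synthetic season generator

The generator emulates the statistical structure the analysis assumes, with
one sub-seeded RNG stream per stage so every stage is individually
reproducible from one master seed.

* **Weather** — independent daily marginals spanning autumn conditions at a
  ~2300 m pass: temperature ~ Normal(11, 4.5) truncated to [−2, 22] °C;
  rainfall ~ Bernoulli(84/191) · Gamma(shape 1.2, mean 3.5 mm); heading ~
  Uniform[0, 360); windspeed ~ Gamma(2, mean 3 m s⁻¹); sunshine ~
  Beta(1.2, 1) · 480 min. The temperature mean was fixed by a one-off
  analytic calculation so that the model's zero probability, averaged over
  the weather distribution at the default coefficients, reproduces the
  observed ~50% zero-migration-day rate; no joint weather distribution is
  claimed.
* **Daily totals** — drawn from the ZINB above at the published coefficient
  table (count: intercept 4.29, headwind 1.36, rainfall −1.26, sunshine
  6.15, temperature 0.56, sunshine:temperature −0.43; zero: intercept 3.02,
  temperature −0.35, rainfall 0.67, headwind −0.73). The dispersion is not
  published; θ = 0.5 is the generator's choice, giving the heavy
  overdispersion characteristic of daily totals spanning zero to millions.
* **Within-day allocation** — multinomial over the 32 video bins with a
  triangular kernel (half-width 2 h) over a 20% uniform background, mode at
  14:45 (345 min after 09:00, ~1 h after solar noon). A full-day triangle
  was rejected: its ~3% peak/neighbour contrast is analytically too small
  for the mean mass-day profile to express the configured peak against
  multinomial noise at realistic totals.
* **Trap catches** — per taxon and day, Poisson abundance split
  south/north binomially with wind-conditional southward probability;
  `tailwind_abundance_factor` lets high-altitude profiles vanish from the
  trap on tailwind days, which is what defines that category operationally.
* **Sunlight occasions** — NB counts whose sunny-class mean is `sun_fold`
  (default 16) times the shaded mean (shade mean 2.0, θ = 1.5, half the
  occasions sunny).
* **Sex ratios** — binomial draws at the documented female fractions
  (65/96/72%) and sample sizes (826/929/1148).

**What the generator does not emulate:** weather autocorrelation and
covariate dependence (hooks exist in config), species phenology within a
season, observation gaps, taxon-specific diurnal timing differences, any
built-in sun effect in the *visual* (butterfly) counts, and spatial
structure (flight paths, radar signatures). Passing tests therefore
demonstrate that the estimators recover the structure they assume, not that
real seasons satisfy those assumptions.

## Problem sizes and numerical tolerances

Default campaigns are 191 days over four seasons, matching the field
design. The simulation-based checks use 100–300 replicates for recovery
studies, 200 for the sunlight contrast and small bootstrap sizes in tests;
likelihood identities are checked to 10⁻⁸ against direct probability
summation, and AIC/F-statistic identities exactly. Degenerate inputs
(all-zero counts, single-class sunlight tables, constant predictors,
all-zero daily totals) raise informative errors rather than propagating
NaNs.

## Known limitations

* Wald standard errors from observed information are mildly anticonservative
  for the count part at n ≈ 191 under θ = 0.5, most visibly for the
  near-collinear sunshine/temperature/interaction block (the recovery test
  computes and reports per-coefficient ±2·SE coverage); profile-likelihood
  or bootstrap intervals are the better-calibrated alternative, and the
  bootstrap bands are the recommended uncertainty summary for predictions.
* The all-subsets search refits every model from scratch; with the default
  cap (4096 models) a full candidate set takes minutes, not seconds.
* Biomass and nutrient fluxes are only as good as the per-taxon mass table;
  the shipped masses are placeholders for the synthetic assemblage.
* The historical trap-area comparison is a fixed ×8 rescaling; it inherits
  all the caveats of comparing different traps, sites and decades.
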