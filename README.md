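# passflow

Quantitative analysis of diurnal insect migration through a mountain-pass
bottleneck.

Narrow high-mountain passes concentrate autumn insect migration so strongly
that the whole flying assemblage — from hoverflies and grass flies to
butterflies and dragonflies — can be counted at ground level. `passflow`
turns the raw observations of such a monitoring campaign (bidirectional
malaise-trap catches, 1-min video transects every 15 min, bi-hourly visual
counts, daily weather) into the quantities ecologists report:

* **Migrant classification.** Per taxon and wind category the *southward
  score* `100·(n_south − n_north)/n_total` (defined at n ≥ 100) separates
  **high-altitude migrants** (headwind score ≥ 90, near-absent from the
  trap in tailwinds), **flight-boundary-layer (FBL) migrants** (tailwind
  score ≥ 50) and non-migratory taxa.
* **Bioflows.** Video counts scale ×225 (time × width) with a missed-insect
  correction (÷0.43), visual counts ×8; migratory traffic rates
  MTR = N/(t·W) in individuals m⁻¹ min⁻¹; seasonal totals, fold variation,
  sex ratios, biomass and N/P nutrient flux, ecological-role percentages
  and historical trap comparisons.
* **Mass-migration days and timing.** The smallest set of top-ranked days
  whose counts reach 95% of the seasonal total, and the mean 15-min diurnal
  profile across them.
* **Weather model.** Daily totals follow a zero-inflated negative binomial:
  a day is a structural zero with probability π = ½ + arctan(z'γ)/π
  (cauchit link) and otherwise NB with mean exp(x'β) and dispersion θ.
  Covariates: headwind index h ∈ [−1, 1], rainfall, sunshine proportion
  s ∈ [0, 1], temperature, windspeed, plus interactions. All-subsets AIC
  selection, mean-AIC variable importance and bootstrap prediction bands.
* **Sunlight.** Sun-present vs sun-absent fold difference with a Welch t on
  log1p counts, and OLS of visual counts on percent sunshine.

A synthetic-season generator (`passflow.synthetic`) draws complete
campaigns with exactly this statistical structure, so the entire pipeline
runs and is tested without any field data.

## Worked example

Generate a four-season campaign and run every stage (also available as the
numbered scripts under `analysis/`):

```sh
python analysis/01_simulate_season.py
python analysis/02_classify_migrants.py
python analysis/04_mass_migration_days.py
python analysis/05_weather_model.py
```

which prints (seed 2021):

```
simulated 191 days over 4 seasons (seed 2021)
52.4% of days had no migration; busiest day: 4,766,151 individuals

       taxon     category  head_n  head_score  tail_n  tail_score
Chironomidae NonMigratory    5321    1.597444    6151   -2.552430
 Chloropidae          FBL   13292   59.298826   15424   60.593880
    Muscidae          FBL    8088   70.524233    9177   59.245941
    Pieridae          FBL     689   77.068215     812   61.330049
   Syrphidae HighAltitude   10609   94.099350      38         NaN

29 of 191 days carry 95.1% of all individuals
mean diurnal profile peaks at 14:45 (averaged over 29 mass-migration days)

ZINB fit (count part log scale, zero part cauchit scale):
                            estimate  std_error  z_value  p_value
count:intercept                4.387      1.218    3.601    0.000
count:headwind                 1.424      0.216    6.603    0.000
count:rainfall                -1.237      0.119  -10.390    0.000
count:sunshine                 5.591      2.061    2.712    0.007
count:temperature              0.541      0.094    5.738    0.000
count:sunshine:temperature    -0.386      0.160   -2.411    0.016
...
theta = 0.695, logLik = -1080.03, AIC = 2182.1
```

Reading this: roughly half of all autumn days show no migration at all
(zero inflation), a handful of mass-migration days carry 95% of the
seasonal flux, movement peaks at 14:45 (about an hour after solar noon),
and the refitted weather model recovers the coefficients the season was
generated from — warm, sunny, rain-free headwind days produce the big
movements. Syrphidae come out as high-altitude migrants (southward score
94 in headwinds, 38 individuals in tailwinds), the other directed taxa as
FBL migrants.

The same stages are available as a CLI (`passflow simulate | classify |
bioflow | massdays | weathermodel | sunlight | run-all`) for file-based
inputs in the documented tab-separated schemas; `passflow run-all` writes
every table plus a report and a manifest with config hash and seeds.

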