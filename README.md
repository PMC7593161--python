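# nestsurv

Daily known-fate survival analysis for incubating ground-nesting birds
monitored by GPS telemetry — built around the incubation ecology of wild
turkeys (*Meleagris gallopavo*), whose females leave the nest on short
"recess" bouts that trade nest attendance against their own predation
risk.

The package turns raw hourly GPS fixes into survival inference in four
stages:

1. **Recess classification** — fixes within 27.5 m of the nest are
   incubation locations; fixes strictly beyond are recess locations.
   Maximal runs of recess fixes are bouts; each nest-day yields a recess
   count, an off-nest duration (1 hourly fix = 1 hr) and a total distance
   traveled.
2. **Daily range size** — a dynamic Brownian bridge movement model
   (sliding window 7, margin 3, location error 20 m) yields a 99%
   utilization-distribution contour area per nest-day.
3. **Bayesian daily survival models** — the exposure day is the sampling
   unit: nest (or female) *i* survives day *j* with probability

   ```
   logit Φ_ij = β0 + β1·attempt_i + β2·conceal_i + β3·distance_ij
              + β4·duration_ij + β5·recess_ij [+ β6·nestage_ij]
              + Year_i + Site_i
   ```

   with Normal(0, precision 0.001) priors on every coefficient and
   random-effect level (site nested within year), sampled by an adaptive
   Metropolis-within-Gibbs sampler (3 chains; 4,000/1,000 iterations and
   burn-in for nests, 7,000/2,000 for females; thinning 3), with
   Gelman–Rubin R-hat diagnostics.
4. **Posterior decision statistics** — quantile tables, 95% highest-density
   intervals, probability of direction (pd, flagged at ≥ 0.9), per-SD odds
   ratios `exp(|β|)`, and period survival = daily survival raised to the
   30-day incubation cycle.

Because the original field data are not required, a first-class synthetic
generator (`nestsurv.simulate`) produces GPS schedules (hourly
05:00–20:00 plus 23:59), recess bouts and fates from a known logit-scale
hazard, calibrated so realized daily behavior matches the study's moments
(1.62 recesses/day SD 1.24; 2.09 hr/day off nest SD 1.80; 357.63 m/day SD
396.58; concealment 92.5 cm SD 47). Every stage is validated against
that ground truth; see `docs/methods.md` for models, calibration and
caveats.

## Worked example

```python
import numpy as np
from nestsurv import (SimParams, make_dataset, build_exposure_table,
                      DailySurvivalModel, McmcConfig)

params = SimParams(n_birds=120, seed=7)
ds = make_dataset(params)
cov, period = build_exposure_table(ds.nests, ds.fixes)

# covariate model (nest survival)
model = DailySurvivalModel.from_dataframe(cov, outcome="nest")
result = model.fit(McmcConfig.nest_default(seed=1))
print(result.summary())
print(result.odds_ratio("duration"))

# period survival from the intercept-only fit on the unfiltered table
pres = DailySurvivalModel.intercept_only(period, outcome="nest").fit(
    McmcConfig.nest_default(seed=2))
daily = pres.daily_survival_draws()
ps = pres.period_survival()
print(f"daily nest survival: {daily.mean():.3f}")
print(f"period (30 d) nest survival: {ps.mean:.2f} "
      f"(95% CrI {ps.quantiles[0.025]:.2f}-{ps.quantiles[0.975]:.2f})")
```

prints (abridged; 190 nests, 52,394 fixes, 3,055 exposure days):

```
             0.025  0.250  0.500  0.750  0.975  mean  hdi_low  hdi_high    pd   rhat
intercept     4.47   5.55   6.20   6.91   8.51  6.28     4.39      8.34  1.00  1.012
attempt      -0.12   0.01   0.08   0.14   0.27  0.08    -0.12      0.27  0.78  1.000
...
duration     -0.31  -0.17  -0.10  -0.02   0.15 -0.09    -0.32      0.14  0.80  1.000
nest_age     -0.61  -0.46  -0.40  -0.33  -0.19 -0.40    -0.59     -0.18  1.00  1.001
1.10 times less likely to survive per SD increase
daily nest survival: 0.955
period (30 d) nest survival: 0.25 (95% CrI 0.19-0.31)
```

Reading the output: each row is one covariate's posterior on the logit
scale per standardized unit — the negative `duration` median says nests
whose females spent more hours off the nest each day survived at lower
daily rates (pd 0.80, below the 0.9 significance flag at this sample
size). Daily survival 0.955 compounds to 0.25 over a 30-day incubation.
The negative `nest_age` coefficient is an artifact of censoring nests
incubated under 3 days (see `docs/methods.md`).

A command-line pipeline wraps the same stages:

```sh
nestsurv run-all --seed 7 --out-dir run/
nestsurv simulate --seed 7 --n-birds 40 --out-dir run/   # or stage by stage
nestsurv metrics --fixes run/fixes.csv --nests run/nests.csv --out-dir run/
nestsurv fit --exposure run/exposure.csv --model both --out-dir run/
nestsurv summarize --draws run/draws_nest.csv --outcome nest --out-dir run/
```

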