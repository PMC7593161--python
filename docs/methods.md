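# Methods

`nestsurv` implements a daily known-fate survival analysis for incubating
ground-nesting birds monitored by GPS telemetry, together with a synthetic
telemetry generator that reproduces the statistical structure the analysis
assumes. This note documents the models, the numerical choices, and what
the synthetic experiments do and do not demonstrate.

## Survival model

The sampling unit is the *exposure day*: nest (or female) *i* alive at the
start of incubation day *j* survives to day *j + 1* with probability
Φ_ij, a Bernoulli trial with

```
logit Φ_ij = β0 + β1·attempt_i + β2·conceal_i + β3·distance_ij
           + β4·duration_ij + β5·recess_ij [+ β6·nestage_ij]
           + Year_i + Site_i
```

The nest-age term appears only in the nest model; the female model shares
the remaining covariates. Detection is perfect (known fate), so the
likelihood is a product of Bernoulli terms over nest-days. Site is nested
within year: each (site, year) pair is a separate random-effect level.
Every coefficient *and* every random-effect level carries an independent
Normal(mean 0, precision 0.001) prior — deliberately, there is no variance
hyperprior, so the "random effects" are effectively weakly-penalized fixed
effects.

Covariates are z-scored by default (per-covariate mean/SD retained), so
coefficients are per-SD effects and `exp(|β|)` is the per-SD odds ratio.
A raw-scale option exists (`standardize_covariates=False`).

### Identifiability and reporting

Because a year's indicator equals the sum of its site-within-year
indicators, the design has exact flat ridges: the raw intercept, the year
levels and the site-level means are confounded under the nearly-flat
priors. Sampling is left unconstrained (as specified), and reporting uses
a hierarchical sum-to-zero convention: per posterior draw, each year's
site-level mean is folded into that year's level and the year-level mean
into the intercept. The folded quantities are identified; the linear
predictor is unchanged. Convergence diagnostics (R-hat, classic
between/within form with the (n−1)/n correction) are computed on the
folded parameterization, because R-hat on a flat ridge measures the random
walk along an unidentified direction rather than anything inferential.

### Sampler

Adaptive Metropolis-within-Gibbs, compiled with numba: componentwise
Gaussian random-walk proposals, with each proposal scale multiplied or
divided by 1.3 every 50 iterations during burn-in to keep acceptance in
30–45%, then frozen (retained draws therefore come from a fixed kernel).
Chains start from dispersed N(0, 1) draws. Defaults follow the study
protocol: 3 chains, 4,000 iterations with 1,000 burn-in for the nest
model, 7,000 with 2,000 burn-in for the female model, thinning 3.
`n_iter` counts total iterations including burn-in. Runs are exactly
reproducible from the seed (per-chain seeds are spawned deterministically).

The intercept-only *period survival* variant is fit on the unfiltered
exposure table (including nests incubated < 3 days, which the covariate
analysis censors); period survival is the elementwise 30th power of the
daily-survival draws.

### Posterior decision statistics

Summaries report the 0.025/0.25/0.5/0.75/0.975 empirical quantiles
(linear interpolation), the mean, the 95% highest-density interval
(shortest window over sorted draws), and the probability of direction
pd = max(P(β > 0), P(β < 0)) with draws at exactly zero split evenly.
pd ≥ 0.9 is flagged as biologically significant. Quantile columns are
printed to 2 decimals in the table output. Predicted period-survival
curves hold other covariates at 0 (their mean after standardization) and
random effects at 0.

## Recess classification and daily metrics

A fix is a *recess* location iff its Euclidean distance from the nest
exceeds 27.5 m strictly; ≤ 27.5 m is a nest location. A recess bout is a
maximal run of consecutive recess fixes within one calendar date (a bout
never spans midnight; the 23:59 → 05:00 gap breaks runs). Daily metrics:

* duration = 1 hr per off-nest fix (the schedule is hourly 05:00–20:00);
  the 23:59 fix contributes a configurable weight (default 1 hr) when off
  nest, since its preceding gap is not hourly;
* recess count = number of bouts;
* distance = sum of Euclidean legs between *all* consecutive fixes,
  including legs between on-nest fixes (sub-buffer GPS scatter).

The exposure-day assembly censors nothing outright but (i) replaces the
behavioral covariates of each nest's first and last incubation days with
that nest's across-day means (movement metrics are unreliable on
transition days), (ii) mean-imputes days with under half the scheduled
fixes, and (iii) excludes nests incubated < 3 days from the covariate
dataset while keeping them for period survival. Fate coding: the last row
of a failed nest is 0, all other rows 1; the female column is 0 on the
last row only when the female was killed; a female exits the risk set
when her nest terminates.

Note one deliberate deviation from a superficially-plausible invariant:
enlarging the buffer can *increase* the bout count (a larger buffer can
turn one run into two by reclassifying an interior fix), so only duration
is monotone in the buffer; the bout count is bounded by the off-nest fix
count instead.

The collinearity screen computes pairwise Pearson correlations among
candidate covariates and drops, from each pair with |r| ≥ 0.7, the member
later in a priority order (distance outranks range size, matching the
source analysis, which removed daily range size at r = 0.74). Downstream
fits adapt their fixed effects to whichever columns survive.

## Dynamic Brownian bridge daily ranges

The Brownian bridge conditions position between consecutive fixes; at
fraction α of a segment of duration T the position is normal around the
linear interpolation with variance
`T·α(1−α)·σ²_m + (1−α)²δ² + α²δ²`, with location error δ = 20 m.
The motion variance σ²_m is estimated in a sliding window (7 fixes,
margin 3) by maximizing the leave-one-out likelihood of the window's odd
interior points; candidate change points at the margin boundaries are
accepted when they lower the BIC (k = 2 variances vs 1, n = number of
leave-one-out points); each fix's σ²_m is averaged over all windows
covering it. The 1-D maximization runs on log σ²_m over [1e−4, 1e8] m²/s
with a bounded scalar minimizer (tolerance 1e−6). Tracks shorter than the
window fall back to one global variance; < 3 fixes is an error.

The UD is the time-integral of the bridge kernels, discretized with 30
midpoint steps per segment (10 is the minimum for the oracle comparisons;
30 brings the two-fix total-variation error under 1e-3) on a 10 m grid
padded by 3.5 bridge SDs (3.0 would clip the 99% contour of an isotropic
kernel, whose radius is 3.035 SD). Masses are normalized to exactly 1.
The daily range size is the area of the smallest set of highest-density
cells reaching 99% cumulative mass, in hectares; an epsilon (1e−9) on the
cumulative threshold guards ties. The motion-variance profile is fitted
once per nest over the whole incubation track — a 7-fix window cannot sit
inside a single day's recess fixes — and the UD is integrated per
calendar day.

## Synthetic data generator

The generator emulates the study design: 278 females across 8 sites and
five seasons, 30-day incubation, 17 fixes per day (hourly 05:00–20:00
plus 23:59), renesting after failure (probability 0.45, attempts capped
at 4), and a small abandonment rate (2%) producing nests incubated < 3
days to exercise the censoring rule. True hazard coefficients default to
the study's reported posterior medians on the per-SD scale (nest
intercept 3.04 ≈ daily survival 0.95; female intercept 5.39), with
year/site random effects of SD 0.25.

### Daily behavior calibration

Daily behavior is i.i.d. across days (the study reports only pooled
moments; within-female repeatability is deliberately not modelled):

* **Duration** (off-nest hours, 0–16): a normal rounded to integers and
  truncated at zero, with (μ, σ) root-found so the discretized
  distribution has mean 2.09 and SD 1.80 exactly.
* **Recesses | duration**: zero iff duration is zero; otherwise a rounded
  truncated normal on [1, min(d, 17−d)] (bouts need on-nest separators)
  whose conditional mean is linear in duration. Its three parameters are
  solved against the pooled mean 1.62, SD 1.24, *and* a
  duration–recess correlation target of 0.65. The correlation is a
  deliberate choice: any model in which bout lengths are independent of
  bout count forces r ≈ 0.9 under the printed moments, yet the source
  analysis retained both covariates past a 0.7 collinearity screen — so
  the real data must exhibit compensation between bout count and bout
  length (days with long total off-time consist of fewer, longer
  forays), and 0.65 encodes that just below the screen threshold.
* **Distance | duration**: the day's realized path equals its geometric
  floor (on-nest scatter path plus one minimal out-and-back per bout)
  plus a Gamma surplus whose mean is linear in duration; the three
  surplus parameters are solved in closed form against the pooled mean
  357.63 m, SD 396.58 m and a distance–duration correlation of 0.5
  (configurable; it gives the collinearity screen structure to detect).

On-nest scatter is an AR(1) chain (φ = 0.95, stationary SD = jitter/3,
clipped to the 10 m jitter radius): an incubating bird is stationary and
consecutive GPS errors share satellite geometry; i.i.d. scatter would add
> 100 m/day of spurious path and break the distance calibration.

Day geometry is solved exactly: bout foray radii are found by root
finding so that the summed consecutive-fix path equals the drawn distance
(to ~1e−9 m), which is why the round-trip test can demand exact recovery
of (recesses, duration, distance) by the classifier.

### What the generator does not emulate

No landscape or habitat structure, no predator process, no weather, no
within-female behavioral repeatability, no seasonal trends, and recess
bouts are trips to a single foray point rather than looping paths.
Passing tests therefore demonstrate correctness of the estimation
machinery under the stated data-generating assumptions, not robustness to
real-field misspecification.

### Pipeline estimates vs generator truth

Two protocol rules — faithfully implemented — make full-pipeline
coefficient estimates differ systematically from the generator's truth,
on synthetic and field data alike:

* replacing death-day covariates by nest means (first/last-day
  imputation) removes most of the covariate signal exactly where the
  information about failure lives, attenuating behavioral coefficients
  toward zero;
* censoring nests incubated < 3 days removes early failures, depressing
  the apparent hazard at low nest ages and inducing a negative nest-age
  artifact even when the true age effect is zero.

The female model is hit hardest: a female killed on the nest dies on her
nest's final day, which is exactly the day whose covariates are
mean-imputed, so with i.i.d. daily behavior (no between-female
repeatability) essentially no covariate signal survives to the female
likelihood and its pipeline coefficients shrink toward zero. In field
data, persistent between-female behavioral differences would flow
through the imputed nest means and remain estimable.

Parameter-recovery tests therefore exercise the survival module on
directly simulated exposure data (covariates as drawn, no imputation),
where the duration coefficient is recovered without bias; the pipeline
tests assert structural round-trips, not coefficient equality.

Two further expectations about the defaults: because the true female
intercept is the covariate-model median (5.39) rather than the published
*average* daily rate (0.99), the realized female mortality (~7–8% of
birds) is below the printed 14% — the two printed numbers are not
mutually consistent under a single logit model, and the generator follows
the coefficient table. Jensen's inequality similarly makes realized
average daily survival slightly lower than `logit⁻¹(intercept)`.

## Problem sizes

Default test and acceptance runs use: 10,000 days for moment checks,
1,000+ days for round-trip checks, 320 exposure days for the conjugate
oracle, 20 replicates of 300 nests × 30 days for recovery, and the full
278-bird study scale for the pipeline run in `scripts/acceptance.py`.

## Known limitations

* The flat-prior random effects make levels with little data nearly
  unidentified; their posteriors are prior-dominated (SD ≈ 31.6) and the
  reported intercept can drift upward in small datasets where many
  site-years contain no failures. This is a property of the specified
  model, not of the sampler.
* With rare events (female deaths), logistic small-sample bias inflates
  coefficient magnitudes; credible intervals remain wide and honest.
* The componentwise sampler is efficient for these designs
  (seconds-to-minutes at study scale) but would mix poorly for strongly
  correlated high-dimensional posteriors; it adapts only during burn-in.
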