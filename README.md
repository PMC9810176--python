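# cptscale

Carcass persistence analysis for post-construction fatality monitoring
(PCFM) at wind energy facilities: interval-censored survival regression of
carcass persistence trials, average-probability-of-persistence estimation
for arbitrary search intervals, and a two-stage mixed-effects model that
scales game bird persistence probabilities up to raptor persistence
probabilities.

## The problem

Fatality rates at wind facilities are estimated from carcass searches
corrected for imperfect detection. One detection-bias component is carcass
persistence: a carcass may be scavenged before the next search. Persistence
is measured with carcass persistence trials (CPT) — fresh carcasses placed
on the landscape and checked on a schedule (typically daily for the first
week, then weekly, over 56 days), so the removal time is only known to lie
in an interval. Pen-raised game birds (pheasants, ducks) are the routine
trial surrogate, but game bird carcasses persist far shorter than large
raptor carcasses. Raptor and eagle fatality estimates built on unadjusted
game bird persistence are therefore biased high. `cptscale` fits the
survival models and provides a statistical bridge from game bird to raptor
persistence.

## The models

**Survival layer.** Removal time T follows a log-location-scale family
(exponential, Weibull, log-logistic, or lognormal): log T = μ + σW, with
categorical covariates (habitat, season, USFWS Region) entering μ linearly
under treatment coding and log σ linearly. Each carcass contributes the
interval-censored likelihood term S(L) − S(R) on its bracketing interval
[L, R), with S(+∞) = 0 for right-censored carcasses. Candidates are ranked
by small-sample corrected AIC (AICc), and the most parsimonious model
within 2 AICc points of the best is selected. From a fitted model the
package reports the median persistence time and the average probability of
persistence over a search interval t,

    r(t) = (1/t) ∫₀ᵗ S(u) du,

with 90% CIs by parametric bootstrap (multivariate-normal draws on the
estimator).

**Scaling layer.** Studies with both bird types are aggregated into
*analysis groups* (same site first, then same state and habitat, never
across states) of at least 8 carcasses per bird type. Per group and bird
type, a survival model is selected and 1,000 bootstrap parameter sets yield
paired draws of (game bird r̂, raptor r̂) for 14-, 30-, 60- and 90-day
intervals. On the pooled pairs a linear mixed-effects model is fit by
maximum likelihood:

    logit(r̂_raptor) = β₀ + β₁·r̂_gamebird + season/Region/habitat offsets
                      + (u₀g + u₁g·r̂_gamebird) + ε,

with correlated random intercept and slope by analysis group and AICc
selection over the fixed-effect subsets (baselines fall, Region 1,
cropland). The fitted model predicts raptor persistence from game bird
persistence for new sites (fixed effects only) or training groups (adding
BLUPs), and is validated by stratified cross-validation (RMSE, Pearson
correlation, proportion of over-predictions, mean absolute error).

## Worked example

Fit a Weibull persistence model to one simulated grassland trial cell
(120 carcasses, daily-then-weekly checks, 56-day trials):

```python
import numpy as np
from cptscale import IntervalCensoredSurvReg, ModelSpec
from cptscale.simulate import (CellSpec, DEFAULT_SCHEDULE,
                               apply_check_schedule, simulate_removal_times)
from cptscale.trials import make_intervals

cell = CellSpec("weibull", np.log(25.0), 0.8, {"habitat": "grassland"}, 120)
times = simulate_removal_times(cell, seed=42)
obs = make_intervals(apply_check_schedule(times, DEFAULT_SCHEDULE, 56.0,
                                          labels=cell.labels))
res = IntervalCensoredSurvReg(obs, ModelSpec("weibull")).fit(seed=0)
print(res.summary())
```

```
Interval-censored survival regression
  model:  weibull: loc ~ 1, scale ~ 1
  n = 120 carcasses, k = 2 parameters
  log-likelihood = -293.978, AICc = 592.059

  coefficient                         estimate   std err
  loc.intercept                         3.1694    0.0715
  logscale.intercept                   -0.3071    0.0751
```

The location estimate 3.169 (log-days; e^3.169 ≈ 23.8 d) and scale 0.74
recover the generating values (log 25 ≈ 3.22, σ = 0.8) within two standard
errors. Derived persistence metrics with bootstrap CIs:

```python
est = res.persistence_estimates([{}], intervals=(30,), n_boot=1000, seed=1)
```

```
 interval  median_days  median_lo  median_hi  r_hat  r_lo  r_hi
       30        18.17     16.026     20.782  0.606 0.561 0.656
```

i.e. half the carcasses are gone by ~18 days, and a carcass placed at a
random time in a 30-day search interval has probability 0.61 (90% CI
0.56–0.66) of persisting to the next search.

Scaling game bird persistence up to raptors with the published
fixed-effect coefficients (fall / Region 3 / cropland, game bird
r̂(30) = 0.31):

```python
from cptscale.scaling import PersistenceScalingResults
model = PersistenceScalingResults.from_coefficients({
    "intercept": -0.66, "gamebird_r": 4.19, "region[R3]": 0.33})
model.predict(0.31, season=None, region="R3", habitat=None)  # -> 0.7249
```

A game bird 30-day persistence probability of 0.31 scales to a predicted
raptor persistence probability of 0.72.

The same chain is available from the shell:

```sh
cptscale simulate --config sim.yaml --out trials.csv --truth truth.json
cptscale scale --trials trials.csv --boot 1000 --seed 1 --out model.json
cptscale predict --model model.json --gamebird-r 0.31 --season fall \
    --region R3 --habitat cropland
```

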