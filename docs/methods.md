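# Methods

## Interval-censored survival regression

### Model

Removal time T of a trial carcass follows a log-location-scale family:
log T = μ + σW with W standard normal (lognormal), logistic
(log-logistic), Gumbel-minimum (Weibull), or the Weibull law with σ fixed
at 1 (exponential). Survival functions:

| family      | S(t)                        | median            |
|-------------|-----------------------------|-------------------|
| exponential | exp(−t/e^μ)                 | e^μ ln 2          |
| Weibull     | exp(−(t/e^μ)^{1/σ})         | e^μ (ln 2)^σ      |
| log-logistic| 1/(1+(t/e^μ)^{1/σ})         | e^μ               |
| lognormal   | 1 − Φ((ln t − μ)/σ)         | e^μ               |

Categorical covariates enter μ linearly under treatment (reference-level)
coding and log σ linearly; reference levels are the alphabetically first
observed level of each covariate, so every other level's coefficient is a
log-scale contrast against it. Interaction columns are products of
main-effect dummies restricted to level pairs actually observed in the
data; predictions for unobserved pairs are refused.

The time origin is carcass placement (day 0) and all times are days. Each
carcass contributes log[S(L) − S(R)] for its bracketing interval [L, R):
in-person checks give [last-present, first-absent); right censoring gives
[last-present, +∞); camera-monitored removals at time t give the narrow
interval [t − δ, t) with δ = 0.04 d (~1 h) by default, so a single
likelihood code path serves both monitoring modes. The log-difference is
computed in log space (log S(L) + log1p(−exp(ΔlogS))), which keeps
far-tail intervals finite; a genuinely zero-mass interval yields +∞ rather
than an exception so optimizers can back off. Identical (interval, design
row) observations are collapsed into weights, so likelihood cost scales
with the number of unique intervals (≈ the number of checks), not
carcasses.

### Fitting and uncertainty

Maximisation uses BFGS from a moment-style start (log interval midpoints,
censored rows imputed at 1.25× their left bound) plus jittered restarts
(default 5), followed by a Nelder-Mead polish. The coefficient covariance
is the inverse observed information (numerical Hessian). Degenerate strata
refuse to fit: fewer than 8 carcasses (the same threshold used when
aggregating studies), fewer than k + 2 observations, or all rows
right-censored (the MLE then sits at the boundary).

Parametric bootstrap: draws are multivariate normal on the estimator
(centred at the estimates with the inverse-information covariance). Scale
coefficients live on the log link, so σ > 0 in every draw. A
non-positive-semidefinite covariance raises; no silent nearest-PSD repair.
CIs for derived quantities (median, r̂) are equal-tailed percentile
intervals of the bootstrap draws at 90% by default.

### Average probability of persistence

r(t) = (1/t)∫₀ᵗ S(u) du is the probability that a carcass arriving at a
uniformly random time within a search interval of length t persists to the
next search. The scalar path uses adaptive quadrature (absolute tolerance
1e−8); bootstrap batches use a fixed 256-node Gauss-Legendre rule
vectorised over draws. Both agree with the exponential closed form
(e^μ/t)(1 − e^{−t/e^μ}) to well below 1e−6 across the parameter ranges
seen in persistence work (e^μ from 2 to 600 days, t from 14 to 90 days);
the suite pins this. Default search intervals are 14, 30, 60 and 90 days —
the range used in eagle fatality monitoring, with 30 days the most common.

### Model selection

AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), with k counting every estimated
coefficient (intercepts included) and n the carcass count (the sampling
unit); n ≤ k + 1 yields +∞ (inadmissible at that sample size). The
selection rule is parsimony-within-2: among candidates within 2 AICc
points of the minimum, the fewest-parameter model wins, with AICc breaking
ties. The rule is deterministic and order-invariant. For multi-study data
the candidate grid crosses the four families with every admissible
combination of season/habitat/Region terms on location and scale; two-way
interactions only, and only with both main effects present in the same
term list (three-way grids explode combinatorially and winning persistence
models in practice carry at most two-way terms).

## Two-stage scaling model

### Stage 0 — analysis groups

Studies with both bird types are aggregated until each group holds ≥ 8
carcasses per bird type: first studies at the same site (alphabetical by
site then study id), then remaining deficient units with others in the
same state and habitat; a deficient leftover folds into an existing
adequate group of the same cell when one exists, and groups never span
states. The precise greedy order is a tie-break the aggregation rule
leaves open; it is fixed as above for determinism. Units that cannot reach
the threshold are excluded with a logged reason.

### Stage 1 — per-group persistence pairs

Per group and bird type the four families are candidates; season enters
(on location and/or scale) only when every season represented in that bird
type's data holds ≥ 8 carcasses. After AICc selection, B = 1,000 bootstrap
parameter sets are drawn and r(t) computed per draw for each season cell
and each interval in {14, 30, 60, 90} d. Game bird and raptor draws are
paired by replicate index within (group, season, interval): the pairing
preserves both marginal uncertainties without inventing cross-correlation
between two independently fitted models. Probabilities are clipped to
[1e−6, 1 − 1e−6] before the logit — r̂ draws of exactly 1 occur for
long-persisting strata and the clipping keeps the response finite with
negligible distortion. Groups where either bird type fails to fit are
dropped with a logged reason.

### Stage 2 — mixed-effects fit

Response: logit of the paired raptor r̂ draws. Fixed effects: intercept,
game bird r̂ (always), and any subset of {season, Region, habitat} — 8
candidate sets, no interactions (sparse Region × habitat coverage makes
interaction cells unidentifiable). Random structure, fixed across
candidates: correlated random intercept and slope by analysis group,
absorbing the group-level estimation uncertainty from Stage 1. Fits use
`statsmodels` MixedLM by maximum likelihood (not REML: fixed effects
differ across candidates, so only ML likelihoods are AICc-comparable); the
winner is reported from the same ML fit. k counts fixed effects + 3
random-effect (co)variances + the residual variance; n is the number of
pair rows. Reference levels are fall, Region 1 and cropland whenever those
labels are present, otherwise the alphabetically first level.

ICC is ambiguous under a random slope; the reported value uses the
declared formula sd_intercept²/(sd_intercept² + resid_sd²) — the share of
residual-level variance attributable to between-group intercept spread at
game bird r̂ = 0 — and the output carries the formula alongside the
number.

Prediction inverts the logit of the linear predictor. Known groups add
their BLUP intercept/slope; new groups use fixed effects only. Optional
intervals simulate the fixed-effect covariance plus, for new groups, the
random-effect law (no residual term: the target is the group-level
persistence probability, not a single bootstrap draw).

### Cross-validation

Stratified by Region × habitat cell: singleton cells always train (the
selected model form must be refittable), every multi-group cell
contributes ≥ 1 random training group, and groups are added until the
training fraction is as close to 52% as the constraints allow. The model
form selected on the full data is refit per split on the training pairs;
each hold-out group's raptor r̂ point estimate is predicted from its game
bird r̂ point estimate with fixed effects only (hold-out groups are new to
the model by construction). Metrics per split: RMSE, Pearson correlation,
proportion of predictions exceeding the out-of-sample estimate, and mean
absolute error. Each split uses an independent child seed, so extending a
run never perturbs earlier splits; failed training fits are recorded and
the run continues.

## Synthetic data

The generator emulates the structure of multi-study persistence datasets:
removal times from the four families; the modal check protocol (days 1–4,
7, 10, 14, then weekly to day 56) with right-censoring at the last check;
camera cells carrying near-exact removal times; game bird cells with
median persistence spread log-uniformly over 2–35 days and σ near 0.9
(game bird medians in curated multi-study data run roughly 2–48 days);
and 8+ carcasses of each bird type per group (default 40, a typical
four-season site deployment).

For the scaling layer the logit-linear law *is* the ground truth: per
group, bivariate-normal random effects (default SDs 0.5 for the intercept
and 2.0 for the slope, matching the magnitude of fitted dispersions) and
per-group-per-interval noise (SD 0.3) perturb the linear predictor at the
four intervals, and the raptor cell's Weibull (μ, σ) is solved by least
squares so its logit r̂ curve matches those targets. The slope and
intercept used to build the targets are the recovery truth for end-to-end
tests. A direct generator (`simulate_scaling_pairs`) also emits Stage-2
regression rows straight from the law for unit-testing the mixed model in
isolation.

What the synthetic data does not emulate: real scavenger dynamics (carcass
size, species, revisits), heterogeneous per-study check schedules and
trial lengths, seasonal imbalance, and model misspecification beyond the
Weibull approximation error in the raptor construction. Passing recovery
tests therefore demonstrate correctness of the estimators under the stated
generating laws, not robustness to every feature of field data.

## Problem sizes and numerical choices

Recovery tests use 100 replicate cells of n = 500 carcasses per family and
200 coverage trials with 500 bootstrap draws; the end-to-end scaling
recovery uses 30 groups × 40 carcasses per bird type with B = 200
bootstrap replicates and 3 pipeline replicates. These sizes give
Monte-Carlo error comfortably below the asserted tolerances while keeping
the default suite fast. Quadrature tolerance is 1e−8 absolute; optimizer
convergence 1e−7 on the gradient with a 1e−10 function-tolerance polish;
percentile CIs interpolate linearly between order statistics; selection
ties break on parameter count then AICc.

## Known limitations

- No semiparametric (Cox) alternative, left truncation, or frailty terms;
  no continuous covariates such as carcass mass or temperature.
- The inverse-information covariance and normal bootstrap understate
  uncertainty near boundaries (e.g. strata with heavy right-censoring
  whose median estimates exceed the trial length).
- Stage-1 bootstrap x-values make the Stage-2 game bird slope a classic
  errors-in-variables regressor; with within-group spread much smaller
  than between-group spread the attenuation is mild, and the random slope
  absorbs most of it, but the fixed slope is not strictly unbiased.
- Analysis-group aggregation is greedy and order-determined; other valid
  groupings exist when many small studies share a state and habitat.
- Predictions are only defined for covariate levels present in the
  training data (unsampled Region × habitat combinations are refused, by
  design).
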