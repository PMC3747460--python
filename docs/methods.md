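# Methods

## The problem

In observational studies of a binary treatment with time-to-event
outcomes, propensity-score (PS) methods are the standard tools for
removing confounding by measured baseline covariates. The hazard
ratio, however, is *non-collapsible*: even without confounding, the
population-average (marginal) hazard ratio differs from the
subject-level (conditional) hazard ratio whenever covariates affect
the hazard. Different PS designs therefore target different
estimands — matching and inverse probability of treatment weighting
(IPTW) estimate marginal hazard ratios, while stratification and
covariate adjustment return conditional-flavored quantities.
`pshazard` provides a simulation framework for quantifying these
differences, together with production-quality implementations of the
estimators themselves.

## Data-generating process

Each simulated cohort has `n` subjects (default 10,000) with ten
independent standard-normal covariates `X1..X10`.

Treatment selection is logistic:

    logit(p_i) = a0 + aW·x1 + aM·x2 + aS·x3 + aW·x4 + aM·x5 + aS·x6 + aVS·x7

with `aW = log 1.25`, `aM = log 1.5`, `aS = log 1.75`, `aVS = log 2`
(weak / moderate / strong / very strong effects). `X1..X3` affect only
treatment (instruments), `X4..X7` affect both treatment and outcome
(confounders), `X8..X10` affect only the outcome. Treatment status is
Bernoulli with subject-specific `p_i`.

The intercept `a0` is chosen so the *expected* prevalence equals the
design value (0.05, 0.10 or 0.25). Because the covariates are
independent standard normals, the covariate part of the linear
predictor is exactly Normal(0, σ²) with σ² the sum of squared slopes,
so `E[expit(a0 + σG)]` is a one-dimensional Gaussian integral; we
evaluate it with 101-node Gauss–Hermite quadrature and solve for `a0`
by bracketed root-finding (absolute tolerance 1e-6 on the probability
scale). The realized per-sample prevalence is then binomial around the
design value — the prevalence is matched in expectation, not forced
per sample.

Event times follow a Weibull proportional-hazards model generated by
inverse-transform of the cumulative hazard:

    LP_i = β_treat·z_i + aW·x4 + aM·x5 + aS·x6 + aVS·x7 + aW·x8 + aM·x9 + aS·x10
    T_i  = ( −log(u_i) / (λ·exp(LP_i)) )^(1/η),   u_i ~ U(0,1)

with `λ = 0.00002` and `η = 2`. Uniform draws come from the open
interval (a zero draw would make `−log u` undefined and is resampled).
**No censoring is generated** — every subject has an observed event.
The estimator modules still carry an event-indicator field so that
they work unchanged on real, censored data.

## Calibrating β_treat to a marginal target

`exp(β_treat)` is a conditional hazard ratio. To simulate data with a
known *marginal* hazard ratio we invert the (monotone) map from
β_treat to the induced marginal log-HR by bisection. At each candidate
β the marginal log-HR is estimated by potential-outcomes simulation:
generate a cohort, draw an event time for every subject with treatment
forced off and another with treatment forced on (independent uniforms
per arm — the two arms need not be coupled for the stacked fit's
expectation), stack the `2n` records, and fit a univariate Cox model
on the arm indicator. The ATE framing uses the whole population; the
ATT framing restricts the stack to subjects whose *realized*
assignment was treatment. The stacked fit deliberately ignores the
within-subject pairing: only the point estimate is consumed.

Bisection starts from the bracket
`log(target) ± (0.5·|log(target)| + 0.1)`, widens it adaptively if the
root is not straddled (error beyond ±5), and stops when the bracket
half-width falls below `tol = 0.005` on the log-HR scale — below the
Monte Carlo noise of the evaluations, so further precision would be
spurious. Defaults: cohorts of `n = 10,000` per evaluation (matching
the main simulation) and 1000 potential-outcome replicates per
evaluation, with a reduced 200-replicate desk mode.

The package ships a JSON cache (`src/pshazard/data/`) holding the 42
calibrations of the reference design (3 prevalences × 7 target HRs ×
{ATE, ATT}), computed by `scripts/build_calibration_cache.py` with the
desk-mode settings (200 replicates per evaluation, seed 0). Scenario
runs look calibrations up there instead of recalibrating; the cache
key records every parameter that affects the value.

The calibrated conditional effect is always farther from the null than
the marginal target (attenuation), e.g. a marginal ATT hazard ratio of
2 at 25% treated requires `β_treat ≈ 1.20` (conditional HR ≈ 3.3).

## The estimators

All nine estimators are Cox regressions for a treatment indicator on
top of a PS conditioning design. The propensity model regresses
treatment on `X4..X10` — the covariates that affect the outcome —
by maximum-likelihood logistic regression (statsmodels).

* **Matching**: 1:1 greedy nearest-neighbor matching without
  replacement on the logit PS, caliper 0.2 × SD of the logit PS.
  Variants: *naive* (model-based SE), *robust* (sandwich SE summed
  within matched pairs), *stratified* (baseline hazard per pair).
  Naive and robust share one point estimate.
* **Stratification** on PS quintiles: *adjusted* (treatment + four
  stratum dummies), *pooled* (five stratum-specific univariate fits,
  averaged), *stratified* (baseline hazard per stratum).
* **IPTW**: weighted univariate Cox fit with unclustered robust SE;
  ATE weights `z/e + (1−z)/(1−e)`, ATT weights `z + e(1−z)/(1−e)`,
  used raw (no truncation or stabilization).
* **Covariate adjustment**: Cox fit on treatment and the PS itself.

### Design choices where the design was open

* *Caliper SD*: the pooled SD `sqrt((s²_treated + s²_untreated)/2)` of
  the logit PS, following the caliper-width literature the matching
  procedure is taken from; the full-sample SD is available as an
  option.
* *Greedy processing order*: random, seeded (options: data order,
  descending PS). Random order is the convention of the widely used
  matching macros and avoids systematic artifacts.
* *Nearest-neighbor ties*: broken toward the lower subject index, for
  determinism.
* *Quintile cut points*: empirical 20/40/60/80th percentiles with
  linear interpolation of order statistics; values equal to a cut
  point fall in the lower stratum. With a continuous PS the dialect is
  immaterial, but it is pinned for reproducibility.
* *Pooling rule* for the stratified-pooled estimator: unweighted mean
  of the stratum log-HRs with `SE = sqrt(Σ SE_k²)/K` (independent
  strata); inverse-variance pooling is available as an option. Strata
  without events in both arms are dropped with a warning (essentially
  never at n = 10,000); fewer than two usable strata is an error.

## The Cox engine

A single partial-likelihood fitter backs all nine estimators:
Newton–Raphson with step-halving, convergence when the score max-norm
drops below 1e-8 (max 100 iterations), Efron handling of tied event
times (ties are almost surely absent in the simulated continuous
times, where a fast vectorized no-tie path applies). Variances:
model-based (inverse observed information) and the Lin–Wei/Binder
sandwich from score residuals, optionally summed within clusters, with
case weights entering both the score and the sandwich. No small-sample
correction is applied to the sandwich. Score residuals use the exact
no-tie expressions (Breslow-form under ties). A coefficient exceeding
15 in absolute value raises an error: the likelihood is numerically
flat there, which in this setting means monotone likelihood (e.g. all
of one arm's events preceding the other's). Confidence intervals are
Wald, `θ̂ ± 1.96·SE` on the log scale.

The engine is verified against a brute-force grid maximization of the
partial likelihood (1e-4), a hand-assembled score-residual sandwich
(1e-10 relative), and lifelines as an independent implementation
(~1e-6, lifelines' own convergence tolerance), across plain,
stratified, weighted, clustered and tied configurations.

## Performance metrics

Per method and scenario, with `θ` the true marginal log-HR and `θ̂_i`
the per-replicate estimates: mean, bias, relative bias `100·bias/θ`
(omitted when `θ = 0`), MSE, mean estimated SE, empirical SD, the
SE/SD ratio (1 = correctly calibrated variance estimation), empirical
95% CI coverage, and mean CI length averaged on the hazard-ratio scale
(log-scale lengths are recorded alongside). Empirical coverage outside
`0.95 ± 1.96·sqrt(0.95·0.05/n_reps)` differs significantly from
nominal (0.9457/0.9543 at 10,000 replicates).

Replicates whose fits fail are dropped per method with a logged
warning; a scenario aborts if more than 5% of its replicates fail.
Each replicate runs on its own seed substream spawned from the
scenario seed, so output is identical for any worker count.

## Replication tiers and what the tests show

The reference design is 21 scenarios (3 prevalences × 7 marginal HRs)
× 10,000 replicates × 10,000 subjects — far beyond a desk run. The
package therefore runs in tiers, selected by `n_reps`:

* CI tier: ~100–200 replicates, used by the test suite;
* reproduction tier: 500–1000 replicates;
* full tier: 10,000 replicates.

Metrics are means whose Monte Carlo error shrinks as `1/sqrt(reps)`,
so the scaled tiers estimate the full-scale summaries with quantified
noise; cohort size stays at 10,000 so per-dataset sampling behavior is
unchanged. At 200 replicates per scenario the grid reproduces the
reference matched-pair yields (within 1%), the mean SE/SD ratios
(1.28 naive / 1.09 robust / 1.0 IPTW-ATE / 1.40 IPTW-ATT, within
±0.05), the everywhere-lower MSE of IPTW-ATT relative to matching,
and the maximum SE-of-the-mean bound (0.00125 at the 10,000-replicate
tier). The *absolute* mean MSEs come out lower than the reference
figures (0.0015 vs 0.0023 matched, 0.0008 vs 0.0017 IPTW-ATT) by a
common additive amount; with SEs structurally pinned by the matched
sample sizes and SDs pinned by the reproduced SE/SD ratios, this gap
is consistent with a per-scenario offset of RMS ≈ 0.03 between the
nominal and achieved generating truth — i.e. looser calibration of
β_treat than this package's 0.005 tolerance — entering squared into
every estimator's MSE alike.

Known limitations, and what passing tests do *not* show: the generator
draws independent normal covariates, a correctly specified logistic
treatment model, proportional hazards, and no censoring. Real data
with correlated or discrete covariates, censoring, or hazard
non-proportionality can behave differently — in particular, quintile
stratification's residual-confounding bias (visible here as a small
positive shift even under a null treatment effect) depends on the
strength and shape of the confounder effects.
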