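# Methods

## The model

`hiermove` estimates a population-level hierarchical Bernoulli-logit
model for a binary movement response derived from satellite telemetry.
For location *i* belonging to individual *j = g(i)*:

    z_i ~ Bernoulli(mu_i)
    logit(mu_i) = beta0 + beta1*Spring_i + beta2*Summer_i + beta3*Winter_i
                  + beta4*L_i + beta5*Sex_i + beta6*MEI_i + u_j
    u_j ~ Normal(0, 1/tau)

Fall is the reference season absorbed by the intercept; `L` is z-scored
body length (constant within an individual); `Sex` is a treatment
contrast (F = 0, M = 1); `MEI` is a slowly varying environmental index.
Priors for the Bayesian fit are vague: `beta_k ~ Normal(0, variance 10)`
(precision 0.1) and `tau ~ Gamma(shape 0.1, rate 0.01)`, so the
precision of the individual intercepts has prior mean 10 and prior
variance 1000. The process standard deviation is `s = 1/sqrt(tau)`.

The same likelihood is also maximized directly, twice: by a Laplace
approximation of the marginal likelihood (the `glmer` route) and by
penalized quasi-likelihood (the `glmmPQL` route). With vague priors the
three routes should agree; the package treats that agreement as a
testable property rather than an assumption.

## Preprocessing

Argos location classes are ranked `D < 3 < 2 < 1 < 0 < A < B < Z`
(deployment fixes are exact positions, hence best; the manufacturer
assigns no accuracy to A/B/Z). Within each tag and UTC calendar day only
the best-ranked fix is kept, ties going to the earliest timestamp; days
without fixes stay absent — tracks are never interpolated. The response
is `z = 1` strictly west of the 125°W meridian (a location exactly on
the boundary codes east). Seasons use the Northern-Hemisphere
meteorological convention (Spring = Mar–May, etc.), continuous
covariates are z-scored with the sample (ddof = 1) standard deviation,
and gridded covariates are averaged over a positional-error box whose
half-widths convert meters to degrees at 111,320 m/degree (scaled by
cos latitude for longitude). Per-class default error radii span the
printed 742–3498 m (longitude) and 326–1265 m (latitude) ranges, best
class smallest; classes with no manufacturer estimate default to the
range midpoint and are user-configurable.

## The sampler

The model statement above is Bayesian; the sampler design is this
package's own. `sample_posterior` runs independent chains of a
Metropolis-within-Gibbs scheme:

- **beta**: joint Gaussian random-walk Metropolis. A scalar proposal
  scale is tuned by Robbins–Monro toward 30% acceptance during the
  adaptation phase; halfway through adaptation the proposal covariance
  switches to the empirical covariance of the adaptation history (scaled
  2.38/sqrt(d)). Five beta sub-steps run per scan: the update costs one
  rank-1 linear-predictor shift, and the beta block carries the
  slowest-mixing directions, so repeating it is the cheapest way to buy
  effective sample size.
- **translation moves**: for every design column that is constant within
  groups (the intercept, length, sex), a move shifts the coefficient by
  delta and every `u_j` by `-delta * v_j` simultaneously. The likelihood
  is exactly invariant, so acceptance depends only on the priors; these
  moves decorrelate the intercept (and other group-level coefficients)
  from the mean of the random intercepts, which is otherwise the
  dominant slow mode of the posterior.
- **u**: independent adaptive scalar random-walk updates for all groups
  at once (each `u_j`'s conditional touches only its own rows, so the
  per-group likelihood deltas vectorize with `np.add.reduceat`).
- **tau**: exact conjugate draw `Gamma(a + N/2, b + sum(u^2)/2)`.

Chains initialize every beta from Uniform(0, 1), `u = 0`, and tau from
its prior. All adaptation freezes after `n_adapt` iterations, so kept
draws come from a fixed Markov kernel; `n_burn` further iterations are
discarded, then every `thin`-th draw is stored. Presets: `desk`
(4 chains, 2000 adapt, 2000 burn, 20,000 iterations, thin 10 — minutes
at n ≈ 3000–10,000) and `paper` (100,000 adapt, 10,000 burn, 500,000
iterations, thin 10). Convergence is monitored with the classic
(non-split) Gelman–Rubin statistic, matching the era of the model;
`split_rhat` is available separately. Polya–Gamma augmentation would
give an exact Gibbs sampler for this model and was considered; the
adaptive-Metropolis design was kept because it requires no extra
dependency and its correctness is pinned by a dense-grid oracle test.

## Priors-only model and prior-influence check

Two data-free modes exist because the two natural readings differ:
`prior_predictive` drops the likelihood entirely and samples beta, tau,
u from the prior hierarchy; `paper_literal` keeps the response but
replaces every covariate with 1, so only the sum of the coefficients is
data-informed. The influence check computes the overlapping coefficient
of kernel density estimates of each coefficient's posterior against its
priors-only distribution; overlap above 0.35 flags the prior as
informative, and flagged variances are multiplied by 10 per round until
unflagged. The 0.35 threshold and factor-10 expansion are package
choices; for reference, two centered normals whose sds differ tenfold
overlap by ≈ 0.20, and identical distributions overlap by 1.

A practical note from the package's own acceptance runs: with
Normal(0, 10) priors, weakly identified group-level coefficients (sex,
length — one value per individual, likelihood SE near 1) are visibly
shrunk relative to the maximum-likelihood fits, the influence check
flags them, and one round of expansion restores agreement within 0.1.
This mirrors the intended use of the check.

## Maximum-likelihood fitters

For a random-intercept-only model the joint mode in `u` separates by
group, so the inner problem is one-dimensional per group and is solved
by a vectorized Newton iteration. The Laplace log-likelihood

    sum_i [z_i eta_i - log(1 + e^eta_i)] - sum_j u_j^2/(2 sigma^2)
    - (1/2) sum_j log(1 + sigma^2 W_j),   W_j = sum_i mu_i(1 - mu_i)

is maximized by BFGS over `(beta, log sigma_u)` with an exact analytic
gradient from implicit differentiation of the mode equations (the
log-determinant contributes third-derivative terms
`sum mu(1-mu)(1-2mu)`); a test verifies the gradient against central
differences at 1e-5 relative tolerance, and the whole fitter against
`lme4::glmer` to ~1e-3. Standard errors come from the observed
information (numerical Hessian of the analytic gradient). A vanishing
variance is reported as converged-at-boundary, not an error.

`marginal_loglik_quadrature` evaluates the marginal likelihood by
adaptive Gauss–Hermite quadrature centered and scaled at each group's
mode; one node reproduces the Laplace value exactly (by construction),
and node-doubling convergence is a tested property. It is the package's
internal accuracy oracle, not a fitter.

PQL iterates the classic working-response scheme: linearize the logit
link, fit the weighted one-variance-component linear mixed model
(Woodbury identities per group; `sigma_u` by REML of the working model
with the binomial scale fixed at phi = 1), repeat until
`max |delta beta| < 1e-6`. No true log-likelihood exists for PQL, so
`loglik` is None and comparisons use estimates only. This variant
differs from `MASS::glmmPQL` in fixing phi = 1 (nlme estimates a
residual scale), which mostly affects the reported `sigma_u`; slope
estimates agree with glmmPQL to ~0.03 on test data. PQL's documented
attenuation of slope magnitudes for binary data with large `sigma_u`
is asserted as a property, not corrected.

## Variable screening

A classification forest of `n_trees` decision trees, each grown on
`samp_per_class` rows per response class drawn without replacement
(class balancing; the full data's class split is typically uneven).
Importance is the unnormalized mean decrease in Gini impurity averaged
over trees; OOB error is scored on rows outside each tree's sample.
Significance comes from permuting the response and refitting the entire
forest `n_perm` times; `p = (1 + #{null >= observed})/(n_perm + 1)`, so
p is never 0 and is bounded below by `1/(n_perm + 1)`. Selection keeps
`p <= alpha` (inclusive at the boundary). Perfect predictors — any
variable a single threshold or category partition classifies perfectly,
such as the longitude the response was cut from — are detected and must
be removed before fitting. Full-scale defaults are 10,000 trees /
1,000 per class / 100 permutations / alpha 0.1; the desk preset shrinks
to 500 trees and 50 permutations.

## Linearity check

Each continuous candidate gets a penalized cubic B-spline smooth
(basis size 10, knots at quantiles, exact integrated-squared-second-
derivative penalty, sum-to-zero centering) in an additive binomial-logit
model with a ridge-penalized per-group intercept block. Smoothing
parameters minimize the Gaussian REML criterion of the working model
under the classic performance iteration: optimize lambda at fixed
working response/weights, re-converge penalized IRLS, alternate. This
approximates full additive-model machinery; on shared test data it
reproduces mgcv's EDF to ~0.2. EDF per term is the trace of its block
of the influence matrix; EDF below 1.5 is the "linear" verdict (an
exactly linear fit sits numerically at 1.0, and the penalty null space
after centering is exactly the straight line, so EDF → 1 as
lambda → infinity and EDF = basis_size − 1 at lambda = 0). The Wald
chi-square per smooth is reported for table parity but never drives the
verdict.

## Synthetic data

The generator emulates the structure of the motivating multi-year shark
SLRT dataset: 34 individuals, Poisson(278)-many daily locations each
(truncated at >= 30) spread over a ~450-day window inside a 2004–2015
calendar; one body length per individual (Normal(200, 25) cm, z-scored
across individuals) and one sex (Bernoulli 0.5); shared environmental
index series as standardized AR(1) processes (coefficient 0.95 on a
daily grid — slowly varying, index-like); moon phase, SST and
chlorophyll columns as realistic non-informative screening candidates.
Responses are drawn from the model above. Default truth
`beta = (-1.0, 0.75, -1.0, 0.0, 1.0, 0.1, -0.5)`, `sigma_u = 2.5` —
fixture values echoing the magnitudes such analyses report.

What the generator does **not** emulate: spatial positions or movement
autocorrelation (rows are conditionally independent given the
covariates and `u_j`), observation error in covariates, tag failure or
duty-cycling gaps beyond random day-sampling. Passing recovery tests
therefore demonstrates correctness of the estimators under the model's
own assumptions, not robustness to their violation — the
autocorrelation question in particular is explicitly out of scope.

## Experiments

**Data paucity**: 25 replicates at retention fractions 75/50/25/10%
(100 subset fits), rows removed by simple random sampling across the
whole table without regard to individuals (subset size
`round(fraction * n)`; groups emptied by subsampling drop out of the
track index). Accuracy = subset estimate minus full-data estimate;
precision = 95% interval width. Per-replicate seeds derive from the
master seed by a counter scheme `(master, fraction_index, replicate)`,
so results are independent of execution order. Replicate failures are
recorded and skipped; more than 20% failures at one fraction aborts.

**Recovery**: `recovery_study` simulates n datasets, fits each with a
pluggable fitter, and reports per-parameter bias, RMSE and 95%-interval
coverage. The desk-scale default is 100 datasets (the headline claim
used 10,000; at 100 the binomial tolerance on coverage is ±0.065).

## Problem sizes used by the checked results

The acceptance computation simulates 34 individuals at ~100 locations
each (n ≈ 3400) and runs the desk preset; recovery uses 100 datasets of
the same size with the Laplace fitter; cross-paradigm agreement and the
paucity experiment use one full-size dataset (34 × ~278, n ≈ 9500).
These sizes were chosen so every check completes in minutes on one
core while preserving the structure (group count, per-group depth) the
claims depend on.

## Known limitations

- The classic Gelman–Rubin diagnostic can miss certain non-stationary
  pathologies that split/rank versions catch; both are available.
- PQL's `sigma_u` is not comparable across PQL variants (phi handling).
- The linearity check's REML is the working-model approximation; its
  EDF can differ from exact-REML machinery by a few tenths on small
  samples.
- Grid covariate extraction assumes rectangular lon/lat grids with
  monotone axes; no great-circle geometry inside the error box.
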