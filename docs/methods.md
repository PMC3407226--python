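# Methods

## The model

For daily respiratory clinic visits `y_ts` of children in district `s` on day
`t`, the package fits an overdispersed Poisson structured additive regression
(STAR):

    y_ts ~ quasi-Poisson(mu_ts),   Var(y_ts) = phi * mu_ts
    log mu_ts = log N_s + beta0 + DOW_t' gamma + DSLI_t' delta
                + f_time(t) + f_temp(temp_t) + f_spat(s)

* `log N_s` — offset, log of the district's child population.
* `gamma` (6 coefficients) — day-of-week indicators Monday..Saturday with
  Sunday as reference; they absorb the clinic-schedule cycle.
* `delta` (8 coefficients) — the dust storm lag index (DSLI): indicators for
  storm days (lag 0) and each of the 7 days after an event's end, with all
  remaining days as reference.  A storm day inside a later event's lag window
  is lag 0 (event membership dominates); a day reachable from several event
  ends takes the smallest lag (most recent exposure), the usual
  distributed-lag convention.
* `f_time`, `f_temp` — cubic P-splines on equidistant knots with a
  second-order random-walk (RW2) penalty, i.e. a second-difference penalty on
  adjacent spline coefficients that leaves constant and linear trends
  unpenalized.
* `f_spat` — district effects with an intrinsic CAR / Markov-random-field
  prior: conditionally, each district's effect is normal around the mean of
  its neighbours with variance `tau2_spat / n_s`.  Its precision structure is
  the adjacency-graph Laplacian.

Each smoothing variance `tau2_j` carries an IG(0.001, 0.001) hyperprior.
Age groups (preschool 0-6, school 7-14, all) are fitted independently, each
with its own population denominator.

## Estimation

Coefficients are posterior modes of the penalized quasi-likelihood, computed
by penalized IWLS (working response `z = eta + (y - mu)/mu`, weights `mu`,
ridge term `lambda_j K_j` with `lambda_j = phi / tau2_j`); for the log link
this is exactly Newton's method on the penalized Poisson log-likelihood, and
a step-halving guard makes every accepted step decrease the penalized
deviance.  The outer loop is the empirical-Bayes/REML fixed point

    tau2_j <- (b_j' K_j b_j + 2 b) / (edf_j - null_j + 2 (a + 1))

— the posterior-mode update under the IG(a, b) hyperprior, whose flat-prior
fixed point coincides with the REML stationary equation for the Gaussian
working model (validated against a restricted-likelihood grid search in the
tests).  `edf_j` is the term's share of the hat-matrix trace and `null_j`
its penalty null-space dimension.  Overdispersion is the Pearson statistic
over residual degrees of freedom, `phi = sum (y-mu)^2/mu / (n - edf)`, and
rescales both the smoothing parameters and the reported covariance
`phi * (X'WX + sum lambda_j K_j)^{-1}`, so all Wald intervals and posterior
probabilities are phi-inflated.

Identifiability: every smooth is reparameterized onto the null space of a
sum-to-zero constraint (weighted by the intercept-model working weights by
default; plain means optionally), so the intercept carries the overall level.
The penalty's remaining null direction (the linear component of an RW2
smooth) stays in the block as an unpenalized coordinate; the MRF term loses
only the constant (one dimension per connected component — the graph must be
connected).  Fitted values are invariant to the constraint weighting.

## Reporting

A dummy coefficient is reported as percent change in relative rate,
`100*(exp(beta) - 1)`, with the 95% CI obtained by transforming
`beta +/- 1.96 se` (Wald on the log scale, then transformed).  District
effects are classified by the marginal Gaussian posterior: positive /
negative when at least 80% of the mass for the relative rate lies above /
below 1, non-significant otherwise.  Classification is per district
(marginal, not joint).

## Defaults and numerical choices

| parameter | default | rationale |
|---|---|---|
| time knots | 1 per ~30 days, floor 20 | the basis must span seasonal variation; at ~190-day spacing a spring-clustered exposure would absorb unmodelled seasonality.  The RW2 penalty prunes unneeded flexibility, so generous knots cost little. |
| temperature knots | 10 interior | a smooth U-shape needs few; config-exposed |
| spline degree | 3 | cubic P-spline practice |
| hyperprior (a, b) | (0.001, 0.001) | weakly informative inverse gamma |
| convergence tol | 1e-6 relative change | coefficients, tau2 and phi jointly |
| iteration caps | 50 inner / 200 outer | non-convergence raises with the trace attached |
| tau2 floor | 1e-8 | warned and clamped |
| zero-eigenvalue tol | 1e-9 x largest | null-space counting |

Indicator columns that never occur (e.g. lag dummies of a storm-free
calendar) are dropped, reducing to the corresponding no-exposure model.
Ties and degenerate inputs (constant covariate, disconnected graph,
duplicate edges, all-zero counts) raise immediately rather than producing a
silently unidentifiable fit.

## The synthetic generator

Real claims data are confidential, so scenarios are generated from the exact
model above: the shipped 1997-2007 Taipei storm calendar (76 events, 172
storm days) or random event placements; day-of-week and lag log-effects from
the reported-effect presets per age group (e.g. Monday +37.64%, lag 0
-3.66% for all children); a smooth trend of annual + semiannual sinusoids
plus a slow polynomial (amplitudes ~0.1-0.25 on the log scale); a centered
quadratic temperature effect (minimum at 24 C, curvature 0.0015 per degC^2
— a common respiratory-epidemiology shape); CAR district effects drawn
spectrally from the intrinsic prior with tau2_spat = 0.02 (giving effects of
roughly +/-0.2, matching the reported spatial-effect range); temperature as
a seasonal sinusoid (mean 23 C, amplitude 6 C) with AR(1) noise; and
gamma-Poisson counts with Var = phi*mu at phi = 2, a typical quasi-Poisson
inflation for clinic-visit counts (the source study does not print its
overdispersion).  The base rate 0.021 visits/child/day places district mean
daily counts in the descriptive 400-1600 range of the original tables.
The generator evaluates the linear predictor from truth functions directly
and shares no design or spline code with the fitter, so recovery experiments
are non-circular.

What the generator does *not* emulate: serial dependence of counts beyond
what the smooth trend induces (no infection dynamics), pollutant
concentrations, ICD-9 subgroup structure, reporting artefacts, or
district-specific exposure levels (one citywide calendar and temperature
series, as in the modelled design).  Passing recovery tests therefore show
the estimator is correct for the stated model class, not that the model is
correct for real claims data.

## Problem sizes used in tests and the acceptance script

The full-scale scenario is 12 districts x 4017 days (48,204 district-days
per age group); one fit takes a few seconds.  Repeated-fit studies use a
scaled-down 3-district x 730-day variant with 14 random 1-3-day events,
mirroring the full design's event density: 20 replicates for CI coverage
(coverage pooled over the 8 lag effects, since per-lag coverage is not
resolvable at 20 replicates) and 100 replicates for the null
(all-effects-zero) calibration of the Wald tests.

## Known limitations

* Empirical-Bayes Gaussian approximation, not MCMC: posterior probabilities
  and CIs ignore hyperparameter uncertainty; no claim of numerical equality
  with any particular MCMC or mixed-model software, only equivalence to the
  stated model class (verified against dense-Newton and grid-REML oracles).
* `phi` scales the covariance globally; quasi-likelihood matches only the
  first two moments of the counts.
* The adjacency fixture is hand-built from the city map and the population
  file is a synthetic stand-in for census denominators.
* No space-time interactions or district-specific lag effects — the
  predictor is strictly additive.
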