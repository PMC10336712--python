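# Methods

This note documents the models, numerical choices and limitations of the
package, in the spirit of a statistical software methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Hierarchical models for historical trial effects

The unit of analysis is one trial comparison: an effect estimate `y_i` on
the log odds-ratio or log hazard-ratio scale with known standard error
`se_i`.  The two scales are pooled in a single column by design (the
reference analysis pools them to preserve sample size); `outcome_type` is
retained so users can subset.  The package-wide sign convention is that
negative log effects favour the new treatment.

Model 1: `y_i ~ N(theta_i, se_i²)`, `theta_i ~ N(mu_A, tau_A²)`,
`mu_A ~ N(M, eta²)`, `tau_A² ~ pi(kappa, nu)`.  Model 2 adds a single
common comparison-type shift `B` (`theta_i ~ N(mu_A + B·X_i, tau_A²)`,
`X = 1` for active-vs-active).  A single shared `B` rather than per-area
coefficients reflects the sparsity of non-dominant areas in data of this
shape; per-area coefficients would be estimable only for the dominant
area.

Heterogeneity-variance families (the distribution is placed on `tau²`,
not `tau`):

* **log-normal (a)** — `log tau² ~ N(kappa, nu²)`; hyperpriors
  `kappa ~ N(0, 1000²)`, `nu ~ U(0, 5)`.
* **gamma (b)** — `tau² ~ Gamma(shape = kappa, scale = nu)`; both
  hyperparameters `~ U(0, 50)`.  The (shape, scale) reading follows the
  stated "shape / scale" hyperprior wording.
* **half-normal (c)** — implemented as a location-shifted half-normal:
  `tau² = kappa + |N(0, nu²)|`, `kappa ~ half-normal(0, 1000²)` truncated
  to [0, 100], `nu ~ U(0, 5)`.  The published specification is ambiguous
  about which parameter the half-normal hyperprior governs; this reading
  is flagged rather than silently assumed, and the family-specific code
  is isolated so an alternative reading is a one-function change.

Remaining hyperpriors: `M ~ N(0, 1000²)`, `eta ~ U(0, 5)`,
`B ~ N(0, 1000²)`.  `log_posterior` returns the fully normalized log
joint density (−inf outside support), which lets tests compare it to an
independently coded density term by term.

## Sampler

No probabilistic-programming backend is required: the model's structure
makes most conditionals conjugate.  `fit()` runs, per chain:

* exact conjugate normal Gibbs updates for `theta`, `mu`, `M` and `B`;
* slice sampling (stepping-out and shrinkage) for `eta`, `kappa`, `nu`;
* log-scale random-walk Metropolis for each `tau_A²`, vectorized across
  areas, with Robbins–Monro step adaptation toward 44% acceptance during
  burn-in only (frozen afterwards, so the retained chain is a valid
  time-homogeneous Markov chain).

Chains are seeded via `SeedSequence(seed).spawn(n_chains)`; identical
settings reproduce draws exactly.  Initial values are dispersed around
method-of-moments estimates.  Default settings mirror the reference
analysis (3 chains, 150,000 retained draws after 50,000 burn-in);
`McmcSettings.test_scale()` (3 × 5,000 after 2,000) is used throughout
the test suite, where the largest fitted problem is 9 areas × 30 records.
Single-area data are refused unless the hierarchy is pinned via
`ModelSpec(fixed=...)`, because cross-area sharing is then undefined.

Diagnostics: classic split-chain potential-scale-reduction (R̂) per
monitored parameter, cross-checked against `arviz.rhat(method="split")`
in the tests; a fit with any R̂ above the threshold (default 1.05) is
*flagged* (`converged = False`), not raised.  Residual deviance is
`sum_i (y_i − theta_i)² / se_i²`; the additive `log(2·pi·se²)` constant is
omitted as it cancels in comparisons.  DIC uses the study-effect focus:
`Dbar` is the posterior mean residual deviance, `pD = Dbar − D(theta_hat)`
at the posterior-mean study effects, `DIC = Dbar + pD` exactly.

Correctness evidence (all in the test suite): agreement of MCMC posterior
means with deterministic grid quadrature on pinned-hyperparameter toys to
0.01; 95% credible-interval coverage of the overall mean across 20
simulate-and-refit replicates; shrinkage of area means between their raw
means and the overall mean; `pD ≈ n` for a saturated pseudo-posterior.

## Synthetic data

`simulate_dataset` draws from exactly the generative process above, with
`se_i` drawn independently of the effects (log-uniform on [0.05, 0.5] by
default — the spread of a typical mixed collection of moderate-to-large
trials) and a per-area Bernoulli comparison-type indicator.  Default
truths are sized like the historical collection on its analysis scale:
`M = −0.1`, `eta = 0.2`, gamma heterogeneity with mean `tau² = 0.06`
(shape 2, scale 0.03, i.e. typical `tau ≈ 0.25`), `B = 0.035`, 9 areas ×
30 records.  A composition-shaped fixture reproduces the historical
table's salient layout (nine areas, ~87.7% of records in one dominant,
mostly active-comparator area) at reduced scale.

What the generator does *not* emulate: publication bias and small-study
effects, correlation between `se_i` and `theta_i`, non-normal within-study
likelihoods, or secular time trends.  Passing recovery tests therefore
show the estimator is calibrated *under the model's own assumptions*, not
that those assumptions hold in any particular historical collection.

## Predictive priors

One `theta_pred` is drawn per retained posterior draw (no inner
multiplicity), so the Monte-Carlo error of summaries is `sd/sqrt(n_draws)`.
Summaries are moment-matched normals (sample sd, n−1 denominator) on the
log scale.  95% intervals use `z = 1.96` — the convention under which the
published per-area intervals recompute exactly from their printed
(mean, sd) pairs — and exact normal quantiles at any other level.  Under
model 2, `"any"` prediction takes the active-vs-inactive baseline
(`X = 0`); paired comparisons use common random numbers, so
active-vs-active minus active-vs-inactive samples equal the `B` draws
exactly.  The `other/unknown` row uses the three-level new-area
prediction and is wider than a typical represented area because it adds
between-area and hyperparameter uncertainty.

## Prior transforms and combination

`apply_log_effect_prior` offers two conventions: `multiply_probability`
(`p_new = p0·e^theta`, the default, which reproduces the published 22%
median recurrence figure from its printed inputs) and `multiply_rate`
(`r_new = −ln(1−p0)·e^theta`, `p_new = 1−e^{−r_new}`, natural when the
prior is nominally a log hazard ratio).  Medians and intervals come from
closed-form log-normal quantiles; samples are returned only for
downstream fitting.  Induced probabilities above 1 under
`multiply_probability` trigger a warning and are truncated.

Gamma fitting is moment matching (`shape = mean²/var`, `rate = mean/var`)
with an optional ML fit.  Moment-matching the induced case-study rate
distribution gives shape ≈ 16.7 — close to, but not exactly, the
published (17.3, 66.1), whose fitting method is unstated; the published
pair is therefore treated as an *input* wherever the case study is
reproduced.  `bayes_combine_normals` is precision-weighted updating
(never widens); `linear_pool` is a weighted normal mixture (never
sharper than the weighted component variances).

## Decision model and EVSI

Three states: recurrence-free, failure (recurrence), dead.  Annual
cycles; cohort age 68; horizon to age 100; no half-cycle correction.
Failure-free → failure per cycle is `1 − exp(−rate·cycle)` with the
control rate fixed at `−ln(0.75)` (75% one-year failure-free survival,
exponential); post-failure disease-specific mortality is `−ln(0.79)/5`
per year.  Background all-cause mortality defaults to **off** (the input
table lists no life-table entry); a constant-rate hook
(`background_mortality_rate`) is provided.  Costs accrue by start-of-cycle
occupancy (surveillance $5,585/yr failure-free, $17,727/yr recurrent,
plus $147.18/yr in the experimental arm while alive); QALYs accrue state
utilities (0.997 / 0.96); everything is discounted at 3%/yr.  PSA draws:
gamma for costs and beta for utilities, moment-matched to the printed
(mean, SE), with a truncated-normal fallback when an SE is infeasible
for a beta.

EVSI is nested Monte Carlo, fully seeded: the outer loop draws a true
treatment-arm rate from the prior, simulates the trial's Poisson
recurrence count on 308 × 2.5 person-years (1:1 allocation; accrual time
is recorded but not modelled), and updates the gamma prior by exact
conjugacy; the inner loop draws PSA parameters (held common across arms
within a draw, which reduces MC variance) and posterior rates.
`EVSI = E_outer[max-arm posterior expected NB] − max-arm prior expected
NB`, with `NB = 150,000·QALY − cost`.  Population scaling multiplies by
`sum_{t=0}^{9} 25,900·1.03^{−t}`; the published population totals imply a
different, underivable effective-population formula, so ours is logged
explicitly and the per-person values are the primary outputs.

### Reconstruction caveat

The published case-study EVSI values ($44,230 noninformative, $24,109
empirical per person) come from a companion Markov model whose cycle,
horizon and mortality conventions are not restated in the source.  Under
the reconstruction above, this package computes ≈ $80,000 and ≈ $10,000
(the acceptance script prints the exact seeded values); the qualitative
conclusion — the empirical prior roughly halves-or-more the apparent
value of research — is reproduced, the dollar magnitudes are not.  Two
findings from our sensitivity analysis are worth recording.  First, the
estimator is not the cause: a semi-analytic computation (the inner
expectation done by quadrature, exploiting that net benefit is linear in
the PSA parameters) matches the nested estimator.  Second, the published
pair is jointly out of reach for this model class: for any decreasing,
convex-or-linear expected-net-benefit curve in the treatment-arm rate,
the prior/posterior geometry of the two priors caps the
empirical-to-noninformative EVSI ratio near 0.38, below the published
0.545; shorter horizons raise the ratio but collapse both magnitudes,
and background mortality moves the noninformative value toward the
published one while halving the empirical one.  Defaults therefore stay
at the documented conventions rather than being adjusted to chase either
printed value.

## Problem sizes and tolerances

Test-suite problem sizes are chosen to make each check sharp but cheap:
MCMC tests run at 3 × 5,000 draws or less; the recovery study uses 20
replicates of 9 × 30 records at 2 × 2,000 retained draws; EVSI checks run
at 1,000 × 1,000 (acceptance) and a few hundred squared (properties),
with MC standard errors reported and all inequalities asserted with
explicit MC slack.  Quadrature oracles use 4,001-point grids over ±4
marginal sds.  Markov occupancy conservation is asserted to 1e−12; the
DIC identity is exact by construction and asserted exactly.
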