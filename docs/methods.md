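# Methods

`tmmp` implements a class of Bayesian temporal models for demographic and
health indicators observed noisily and sparsely in many populations at
once. This note records the model class, the estimation machinery, the
synthetic-data generator that the tests are built on, and the numerical
and design choices a maintainer would want to know about.

## The model class

For populations c = 1..C on an integer time grid t = 1..T (with an
optional projection horizon T*), the latent indicator eta_{c,t} evolves
according to a **process model** that is additive on a transformed scale:

    g1(eta_{c,t}) = g2(X_{c,t}, beta) + g3(t, eta, alpha_c) + a_{c,t} + eps_{c,t}

- **g1** is one of identity, log, log10, logit. Transforms are exact maps
  with open domains; out-of-domain values raise rather than clamp.
- **g2** is a covariate component: none, linear (population intercept plus
  shared slopes), the log10-of-exponential form used for under-five
  mortality regressions on income/education/HIV, a piecewise-linear
  function of under-five mortality used for the neonatal ratio, or a
  linear combination of principal components of standard mortality age
  schedules.
- **g3** is a parametric systematic component: none, a population-specific
  linear trend alpha_{c,0} + alpha_{c,1}(t − t*), a logistic transition
  toward an asymptote (contraceptive-use dynamics), or a trapezoid pulse
  (sex-ratio inflation).
- **a_{c,t}** is a fixed offset on the transformed scale, default zero,
  e.g. constructed by smoothing residuals of a separate covariate fit.
- **eps_{c,t}** is the stochastic smoothing component below.

Observations y_i attach to latent cells through a **data model**: normal
(mean eta, per-record or estimated sd), logit-normal (Gaussian on the
logit scale with the change-of-variables Jacobian), binomial, or negative
binomial. The negative binomial is parametrized by its mean n*eta and an
overdispersion phi with variance mean·(1 + mean/phi) (NB2); this is stated
prominently because "negative binomial" is a known dialect hazard.
Records carry their own design-based sampling sd when available;
otherwise one sd per source label (or one global sd) is estimated.

## Smoothing component

eps_c = B_c delta_c with B_c either the identity or a cubic B-spline basis
on uniformly spaced knots (default spacing 2.5 grid units, with `degree`
extra uniformly continued exterior knots on each side, *not* clamped
knots — so extending the span for projection appends columns without
changing existing ones). The r-th differences of delta_c are multivariate
normal with a stationary Toeplitz covariance built from a kernel:
AR(1), squared exponential, Matérn (Bessel-function form with exact
shortcuts at nu = 1/2, 3/2, 5/2), stationary ARMA(1,1) (parametrized by
its stationary sd, not the innovation sd), or independent (IID).

For r > 0 the level (and slope, for r = 2) of delta are not identified by
the differenced prior; two anchoring modes are provided:

- `minimum_norm`: delta = D'(DD')^{-1} gamma, the pseudoinverse recovery,
  orthogonal to the null space of the differencing matrix D;
- `anchored`: the unique solution satisfying explicit index-set equations
  sum_{k in K_d} diff^d(delta)_k = 0 for d < r (e.g. a reference
  coefficient pinned at zero, or a sum-to-zero constraint).

The two modes are *not* identical and the zoo records which each model
uses. D is oriented (K−r) × K so that D delta = diff^r(delta); the
published descriptions print the transposed shape, which does not
type-check against the recovery formula.

Covariance factorizations add a single jitter of 1e-10·s(0) to the
diagonal; a factorization that still fails raises with the offending
eigenvalue rather than silently regularizing further.

## Posterior computation

There is no probabilistic-programming backend here; the sampler is a
blocked Metropolis-within-Gibbs scheme written for this model class:

1. **Coefficient blocks** (trend coefficients, covariate intercepts,
   differenced smoothing coefficients gamma; per population) have Gaussian
   priors and enter the transformed-scale mean linearly. They are updated
   by Gauss–Newton Laplace *independence* proposals: a damped Newton
   iteration from a deterministic start (a Gaussianized pseudo-data solve
   where the data model allows it) locates the conditional mode and
   Fisher curvature; a Gaussian proposal there is accepted with a
   Metropolis ratio. When the data model is Gaussian on the transformed
   scale the proposal *is* the full conditional and acceptance is exactly
   one (plain Gibbs); for log-link normal data the acceptance is near one.
2. **Kernel scales and shapes** (and the other hyperparameters that
   coefficient priors depend on) use adaptive random-walk proposals that
   jointly refresh the affected coefficient blocks from their Laplace
   conditionals under the proposed value. In the Gaussian case the
   coefficients integrate out exactly and the move is marginal MH; this
   removes the funnel coupling between a scale and its coefficients that
   makes naive Gibbs alternation diverge. A scale-expansion move on the
   hierarchy of log kernel scales (rescaling all populations'
   standardized deviations together with the hierarchy sd) breaks the
   remaining funnel between the hierarchy scale and its children.  Scales
   with particularly weak likelihood information additionally get an
   ancillarity/sufficiency interweaving pair: a rescaling move (scale and
   standardized deviations move together; only the likelihood enters the
   ratio) alternated with a conditional slice update given the
   deviations.
3. **Hierarchy group means** are conjugate normal draws; hierarchy sds are
   slice-sampled on the log scale (tuning-free, robust to the wide
   conditionals that arise when children are weakly informed).
4. **Shared covariate slopes** get both a Laplace conditional update and
   joint moves whose proposal covariance is learned from the warmup
   trajectory and frozen afterwards (the same adaptive-covariance proposal
   drives the joint logistic-parameter moves); shared
   covariate columns are centred by their global mean (an exact
   reparametrization, undone in the recorded draws) to reduce
   intercept/slope collinearity.
5. The **logistic transition** parameters (asymptote, rate, level at the
   reference year; bounded parameters via scaled inverse-logit) are
   updated componentwise and jointly, always with a refresh of the AR(1)
   deviations; populations without data get exact prior draws.
6. The **subnational** model's county coefficient blocks have
   block-diagonal-in-time conditionals (each observation touches one
   year) and are updated with batched (T, P, P) factorizations; the
   component mean paths mu_p are exact Gaussian draws under their RW(2)
   prior (plus a weak N(0, 10^2) ridge that makes the improper prior
   proper); sigma_p and sigma_mu moves refresh the blocks they control.

Default run: 4 chains × 1000 draws after 1000 warmup (adaptive moves tune
only during warmup), seeded via `numpy.random.SeedSequence`; the same
(seed, config) pair reproduces draws bitwise on one platform. Populations
with no observations receive prior-predictive draws of the latent field.
Split-Rhat and bulk ESS are computed with ArviZ; any Rhat above 1.05
attaches a warning to the returned posterior. Rhat is reported only with
at least two chains.

The latent field is parametrized through the free differenced
coefficients plus the constraint-mode recovery map, so anchoring
constraints hold exactly in every draw.

Limitations of the sampler: the epsilon-inclusive form of the logistic
recursion (deviations feeding back into the transition, which is how the
generator and the projection propagate it) is not supported in fitting —
the fitter uses the systematic-only recursion, so a fit to data generated
with feedback is mildly misspecified. Binomial and negative-binomial data
models ride on the same Laplace machinery via Fisher weights; they are
exercised at small scale only. The piecewise covariate's change point is
a fixed (configurable) value, not estimated.

## Projections

The default projection extends each posterior draw with the estimation
model itself: extend the basis over 1..T* (extra knots at the same
spacing), draw the new r-th order differenced coefficients from their
closed-form Gaussian conditional given the estimated ones, rebuild levels
by undifferencing, and evaluate the deterministic components to T*
(covariates must be supplied to T*; covariate projection itself is out of
scope). For r = 0 kernels the projected variance approaches the
stationary variance; for random-walk smoothers it grows without bound.

The logarithmic-pooling variant for spline RW(2) smoothers draws
projected second differences from N(Gamma_k, Theta_k) with
Gamma_k = W·G + (1−W)·(previous realized second difference) and
Theta_k = W·V + (1−W)·Theta_{k−1}, Theta started at the population's own
smoothing variance. G and V default to the median and variance of
posterior-median estimation-period second differences pooled across all
populations and coefficients (config-overridable); W is a fixed input.
Note that with W = 0 this is *not* the default RW(2) law: the second
differences random-walk from the last estimated difference rather than
being drawn independently around zero. The two laws coincide only in the
first projected step when the last estimated difference is zero; the
tests assert exactly that, plus the W = 1 collapse to N(G, V).

## Synthetic data and what it does (not) show

The generator draws the latent field from the process model (per-population
streams keyed by (seed, population index), so results do not depend on
population order; a master seed splits into truth and noise streams) and
observations from the data model on a user-specified or randomized
missingness design. The default study conditions mirror the data situation
the class targets: 15 populations, 30 years, about 40% of population-years
observed, two source types with relative sampling sds 0.03 and 0.09
(ratio 1:3), and one population entirely unobserved. The generator never
calls the posterior-sampling code, so recovery experiments are not
circular.

The zoo ships matched synthetic scenarios (default 5 populations, 20
years) with placeholder parameter values of realistic magnitude — e.g.
under-five mortality around 60 per 1000 declining ~3%/year with spline
sds around 0.04 on the log scale; contraceptive-use asymptotes 0.7–0.85
with transitions inside the observation window. These values are NOT the
published estimates of any real model. What passing recovery and zoo
tests show is that the machinery is self-consistent — data generated from
a known model are recovered with close-to-nominal uncertainty. They do
not validate the substantive models against real survey or vital
registration data, which carry source-specific biases, survey design
effects and preprocessing steps that the generator deliberately does not
emulate.

The subnational scenario uses 6 age groups against 3 principal
components; with as many ages as components the county coefficients could
interpolate the data exactly and the split between coefficient deviations
and residual noise would be unidentified.

## Parameter estimation strategies

Any parameter can be fixed (with a recorded provenance note), given a
prior, or pooled hierarchically across populations through nested normal
levels (population → subregion → region → world, or any prefix).
Default vague priors, overridable in the configuration: Normal(0, 10^2)
for unbounded locations on the transformed scale, Half-Normal(0, 5^2) for
scales, Uniform(0,1) for AR coefficients rho, Uniform(−1,0) for MA
coefficients theta. The smoothing-variance hierarchies operate on
log sigma (the sources describe a normal hierarchy on the variances
without fixing a scale; the log scale keeps positivity and is standard
practice). The maternal-mortality variance structure
sigma_c = sigma_w(1 + lambda_c), lambda_c ~ TruncNormal(0, sigma_lambda^2)
on (−1, 2), keeps every population sd in (0, 3 sigma_w); the unstated
world-level prior on sigma_w defaults to Half-Normal(5).

## Problem sizes in the shipped checks

The test suite and the acceptance script scale the heavier studies to
sizes a single CPU handles comfortably while keeping the study conditions
above: the recovery study uses the 10-population/30-year spline-RW(2)
scenario with 50 simulations in the tests (25 in the acceptance script)
at one chain of 300 retained draws per fit — the sampler's near-exact
block updates make short chains usable; the zoo convergence checks run
two chains of 400–1000 retained draws per model. The ARMA(1,1) oracle
simulates 200 000 paths.

## Known limitations

- One inference backend (the Gibbs scheme above); no INLA/TMB or
  variational alternatives, and no gradient-based PPL.
- No measurement-bias components in the data models (bias adjustment is
  deliberately out of scope), no correlated observation errors, no
  spatial (CAR/ICAR) smoothing, no non-stationary kernels.
- The simplified offset pipeline for the under-five mortality zoo entry
  smooths raw residuals of a fixed-effect covariate fit; the original
  multi-stage procedure's per-source mixed-effects bias adjustment is not
  reproduced, and its temporal weighting function is a user-supplied
  Gaussian bandwidth because the original is not fully specified.
- B-spline spans are shared across populations (the full estimation
  period) rather than per-population observation windows.
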