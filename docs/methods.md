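# Methods

`envineq` implements a small-area environmental health-inequality analysis:
a spatio-temporal ecological Poisson regression of neighborhood death
counts on socioeconomic covariates and environmental hazards, with a
misalignment-corrected exposure stage and quintile-based assessments of
differential exposure and differential susceptibility.  Everything runs
end to end on a synthetic city, so every statistical claim the package
makes is backed by a test or by `scripts/acceptance.py`.

## The health model

For one sex, deaths in neighborhood *i* and year *t* are

    O_it ~ Poisson(mu_it * Pop_it)

    log mu_it = x_it' beta + S_i + alpha_i + T_t + eta_it

with fixed effects `x_it` containing an intercept, income-quintile dummies
(quintiles rebuilt within each year, first quintile as reference), the
hazard terms (one pollutant plus three noise dayparts, or a binary
polluted-neighborhood indicator in the summary form), quintile-by-hazard
interactions, housing prices, the foreigners share, six land-use
covariates and the two age-structure regressors.  Crude rates with a
`log Pop_it` offset plus age-structure regressors avoid the mutual
standardization problem that arises when an age-standardized rate is
regressed on unstandardized predictors.

Random effects: `S` is a Matern-type GMRF on the area adjacency graph
(SPDE-style precision `(kappa^2 D + L)' D^-1 (kappa^2 D + L)`, `kappa =
sqrt(8)/range`, rescaled so its average marginal variance is the square of
an interpretable `sd`); `alpha` is iid area heterogeneity; `T` is a
first-order random walk over years with a sum-to-zero constraint; `eta` is
iid area-year interaction.  `S` and `T` carry soft sum-to-zero terms and an
explicit global intercept is included — the predictor is otherwise
unidentified.  We read the unstructured `alpha` as area-indexed (matching
its subscript) and let `eta` carry the area-year heterogeneity.

Precision hyperparameters get penalised-complexity priors,
`P(sd > u) = alpha_tail` with defaults `u = 1, alpha_tail = 0.01`; the
spatial range gets a log-normal prior with median 0.3 (a typical
inter-neighborhood correlation scale on the unit-square city) and log-sd 1.
The joint PC prior on (range, sd) is deliberately not implemented.

### Inference

`laplace` (default): Newton iterations find the joint mode of the latent
field given hyperparameters; hyperparameters maximise the
Laplace-approximate marginal likelihood (Nelder-Mead on the log scale,
warm-started inner Newton).  Because `eta` has one entry per observation,
the Newton step is taken through the Schur complement on the structured
block — per-iteration cost O(n m^2) with m ≈ 190 instead of O((m+n)^3).
This is empirical-Bayes Laplace: hyperparameters are fixed at their modal
values rather than integrated over.  To compensate, the fixed-effect
covariance carries a first-order (Kass–Steffey) inflation, J C J' with J
the finite-difference sensitivity of the posterior mean to the log
hyperparameters and C the inverse curvature of the marginal at its mode
(flat directions capped at sd 2 on the log scale).

`mcmc`: Metropolis-within-Gibbs.  The structured block uses a
one-step-Newton (weighted-least-squares) Gaussian proposal that re-centres
at every iteration, `eta` updates componentwise (a posteriori independent
given the structured block), hyperparameters use log-scale random walks
adapted toward 20–40% acceptance during burn-in.  Two chains; split R-hat
and effective sample size via `arviz`.  MCMC is the cross-check route; the
replicate experiments use the Laplace path.

Relative risks are `exp` of posterior quantiles; coefficients of z-scored
covariates are rescaled so the reported RR is per one unit of the raw
covariate.  A term is flagged when its 90% or 95% interval excludes 1,
and reported as `0.794 (0.632–1.002)`.

## Exposure stage and the change-of-support problem

Pollutants are observed at a handful of point stations, noise only as 5-dB
isoline bands, while the outcome lives on areal units.

* **Stations.**  One exact Gaussian-process regression per year, Matern
  covariance with smoothness fixed at nu = 3/2 (closed form), a planar
  trend estimated by GLS (universal kriging), and hyperparameters (range,
  marginal sd, nugget sd) by penalized maximum marginal likelihood with a
  weak log-normal range penalty.  The planar trend matters: a constant-mean
  GP must absorb city-scale gradients into the stationary field, and with
  ~13 stations the MLE then flattens the predicted surface erratically.
  Predictions at neighborhood centroids return the full joint predictive
  law (cross-centroid covariance included).
* **Noise bands.**  Per area, year and daypart, the predictive law is the
  area-weighted mixture of uniforms on the overlapping bands: mean =
  weighted band midpoint, sd = the full mixture sd (`band/sqrt(12)` when a
  single band covers the area).  The mixture sd, rather than the weighted
  within-band sd, is the choice consistent with the package's own draw
  interface (draw moments must converge to the stored moments).
  Unbounded top/bottom bands are clamped to the observed extremes plus
  half a band.  The three daypart surfaces are generated as a shared base
  field plus level offsets plus a small independent deviation per daypart;
  an exact offset-only construction would make the three z-scored
  regressors identical and the daypart coefficients unidentifiable.

`assemble_hazard_draws` builds M complete exposure tables (draw 0 is the
plug-in, posterior-mean table); each hazard's stream is seeded from the
hazard name, so adding or reordering hazards never perturbs the others.

### Propagating exposure uncertainty

Plugging posterior-mean predictions into the health model ignores
prediction error.  Two consequences, both demonstrated by the shipped
experiments: the hazard coefficient is attenuated toward zero (the
estimated trend and hyperparameters inject classical measurement error),
and its uncertainty is understated.

Equal-weight multiple imputation — fit per exposure draw, pool the
posteriors as a mixture — propagates the *uncertainty* but provably cannot
repair the *point estimate*: each draw adds classical error, so per-draw
coefficients are attenuated at least as much as the plug-in.  The package
therefore approximates the joint exposure–health posterior by
sampling-importance-resampling (`fit_over_exposure_draws(scheme="sir")`):
exposure draws are independent across years, so year blocks are reweighted
by the Poisson likelihood of that year's deaths at the current coefficient
estimate, resampled into complete tables, refitted, pooled, and iterated
three times.  The proposal bank (default in the experiments: 300 joint
draws) is a Monte Carlo resolution knob: too small a bank makes the tilt
coarse and the correction disappears.  Feeding the death counts back into
the exposure distribution is exactly what the plug-in and equal-weight
schemes lack, and it is what moves the pooled estimate strictly closer to
the truth in the attenuation experiment.  Equal-weight and
evidence-weighted pooling remain available as `scheme="equal" | "evidence"`.

## Inequality assessments

* **Differential exposure.**  Kruskal–Wallis H (tie-corrected, via
  `scipy.stats.kruskal`; the degenerate all-identical case returns H = 0,
  p = 1 by documented convention) on posterior-mean predictions across
  yearly income quintiles, plus a penalized cubic B-spline smooth of
  predicted exposure on income.  The smooth uses a first-order difference
  penalty (null space = constants, so the effective dof approaches 1 under
  the null), GCV over a log-spaced grid for the penalty weight, and a
  Wald-type chi-square of the penalized fit against the constant model on
  `max(edf - 1, 1)` degrees of freedom.
* **Differential susceptibility.**  A neighborhood-year is "polluted" when
  its predicted hazard levels fall in the top two yearly quintiles — for
  every listed hazard (rule `"all"`, the literal reading) or for at least
  one (`"any"`).  Both rules ship because the source convention is
  ambiguous about joint vs marginal quintile membership; every report
  records which rule was used.  The summary regression then estimates the
  indicator main effect and its quintile interactions; the report lists
  rows in the conventional order (indicator main effect, quintile main
  effects, interactions) with reference rows at RR = 1 and flags terms
  whose posterior is too diffuse to estimate (e.g. an all-zero indicator).

## The synthetic city

The generator emulates the statistical structure of a compact European
city of 73 neighborhoods over 8 years:

* Voronoi tessellation of the unit square from jittered-grid points
  (~101 km^2 physical scale); adjacency by shared boundary.
* Income as a spatially smooth log-normal field with an affluence axis,
  AR(1)-persistent over years, rescaled so the across-area mean is exactly
  100 each year (observed range roughly 30–280; dispersion calibrated to a
  coefficient of variation near 0.4).  Housing prices and the foreigners
  share are tied to income by a Gaussian copula (+0.6 / −0.6 by default);
  land-use shares come from a Dirichlet whose residential component is
  dropped; populations are log-normal with median ~20,000 per area, so a
  baseline rate of 1% yields crude death rates near 100 per 10,000.
* Hazard surfaces: intercept + income-gradient term (on the standardized
  income of the containing area) + a Matern(3/2) field on a fine lattice,
  AR(1) innovations across years.  Stations sample fixed lattice points
  with iid Gaussian error; noise surfaces are quantized into half-open
  5-dB bands whose polygons are unions of lattice cells.
* Death counts are simulated through the *fitter's own* design-matrix
  code path (identical quintile, standardisation and interaction
  definitions), with random effects drawn from their priors at the truth's
  hyperparameters (defaults: spatial sd 0.1, range 0.3, iid 0.05, RW1
  0.05, interaction 0.05).

What the generator does not emulate: real street-network geometry, true
land-use/pollution coupling, migration, within-area heterogeneity, or
missing data.  Passing tests therefore demonstrate statistical
correctness of the estimators under the assumed generative structure, not
robustness to the many ways real city data violate it.

## Experiment design notes

* **Parameter recovery** (73 areas x 8 years, 20 replicates): all
  generative effects are checked for 95% coverage.  The smooth exposure
  surface (income gradient −2, range 0.3) deliberately aliases with the
  Matern spatial effect; the resulting spatial confounding leaves the
  pollutant main effect unbiased but with posterior sd ~25% below its
  frequentist spread, i.e. ~87% effective coverage — a known limitation of
  ecological regression with smooth exposures, not an implementation
  artifact.  The headline quintile and interaction effects are unaffected.
* **KW calibration vs spatial correlation.**  The rank test's nominal
  level only means something under exchangeability.  On kriged predictions
  (correlated across areas through shared stations) the test is
  intrinsically liberal — we measured 13% rejection at microscale truth
  and 80% at smooth truth.  The calibration arm of the detection
  experiment therefore uses an exchangeable null (microscale range,
  no temporal persistence, areal truth); the power arm runs the full
  station → GP → centroid pipeline.  This liberality equally affects any
  analysis that feeds kriged surfaces into rank tests.
* **Problem sizes** were chosen so the full suite and the reproduction
  script each complete in minutes on a single CPU: 20 replicates for
  coverage experiments, 50 for rate estimates, a 300-draw SIR bank, 1000
  null replicates for the KW calibration.

## Numerical choices

* Linear predictors are capped at |30| inside Newton/MCMC to guard
  overflow far from the mode; gradients converge to 1e-9 relative to the
  total count.
* GMRF precisions carry 1e-10 diagonal jitter; GP covariances likewise.
* Quintile ties break by stable rank order, lower-income groups take the
  extra members (73 → 15/15/15/14/14).
* Nelder-Mead hyperparameter search uses at most 150 marginal evaluations
  (warm-started inner Newton makes each evaluation a few milliseconds).
* All randomness derives from a single master seed via
  `SeedSequence(master, crc32(label))`, so components are independent and
  insensitive to the presence or order of other components.

## Known limitations

* Empirical-Bayes Laplace understates hyperparameter uncertainty beyond
  the first-order correction; full integration over hyperparameters is not
  attempted.
* Spatial confounding between smooth exposures and the spatial random
  effect is not corrected (no restricted-regression option).
* The SIR propagation conditions on the fitted GP hyperparameters; their
  estimation error is not re-propagated.
* Sexes are modelled strictly separately; there is no shared-component or
  combined model.
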