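# Methods

This note records the modelling assumptions, the generator's study
conditions, the numerical choices, and the known limitations of the
package.  Notation follows the README.

## Two-stage structure and the cut

The design stage (confounder up-scaling + score estimation) and the
analysis stage (health-effect regression) are deliberately *not* one joint
posterior.  The design stage is fitted first; its posterior mean and
variance of the in-sample score, `(Zhat^(0), sigma2hat)`, are passed to the
analysis stage as fixed data parameterising the uncertainty model
`Z*^(0) ~ N(Zhat^(0), sigma2hat)`.  Outcome information therefore never
flows back into score estimation (a "cut"), while first-stage uncertainty
still propagates forward.  Within the analysis stage the outcome,
uncertainty, imputation and selection submodels are one joint posterior, so
the outcome data do feed back into the *imputed* out-of-sample scores.

Within the imputation (and selection) likelihoods the in-sample score is
pinned at `Zhat^(0)` rather than using the latent `Z*^(0)`; the alternative
latent reading is available via `ImputationModelSpec(in_sample="latent")`.

## Score identifiability and centring

The score enters both stages only through terms that absorb affine maps
(`delta_0`/`delta_C` upstream, the outcome intercept and `f` downstream),
so its level and scale are not identified.  Concretely, the level of
`M'delta_M` trades against `delta_0`, and for bounded (Beta/Bernoulli)
confounders the coefficient-level swings are large.  Each retained score
draw is therefore centred over the in-sample areas before summarising.
Without centring, the reported per-area score variances are inflated by an
order of magnitude by the unidentified common level, and the uncertainty
model then wrongly treats that shared level noise as independent area-level
error, attenuating the score term and biasing the exposure effect toward
the naive estimate.  Comparisons with a generating truth are made after
affine alignment (correlation, or regression of truth on estimate).

## Priors

* Regression coefficients: N(0, 10) in the analysis stage, N(0, 100) in
  the exposure model; precisions of the exposure and imputation residuals:
  Gamma(1, 0.1).
* MICAR precision: Wishart_K(v, B) with `v = K + 1` by default (any
  `v > K - 1` is accepted; smaller values are rejected at build time) and
  `B` the inverse of the empirical correlation matrix of the pooled survey
  records (ridge 1e-6), the only data-driven reading available.  The
  Wishart update is conjugate with degrees of freedom `v + S - c` (`c` =
  number of graph components) and rate `B + xi' Q xi`, `Q` the
  neighbour-graph Laplacian.
* ICAR variance of the imputation field: Inverse-Gamma(2, 1), proper but
  weakly informative.
* Heterogeneity variance `sigma2_theta`: Inverse-Gamma(0.5, 0.0005), the
  standard weakly informative disease-mapping choice.  A heavier-rate prior
  (e.g. IG(2, 1)) floors the posterior well above small true heterogeneity,
  inflating every interval and weakening the coupling between the latent
  score and the outcome; with IG(0.5, 0.0005) the posterior tracks the
  generator's small heterogeneity correctly.
* Flat intercepts `nu_k` are implemented as genuinely flat (no prior term);
  identifiability comes from the per-draw sum-to-zero centring of each
  `xi` column, whose subtracted mean is added back into `nu_k` so the
  likelihood is untouched.

## Sampling

All samplers are model-specific Metropolis-within-Gibbs schemes:

* Regression blocks (Poisson): Gamerman-style IWLS proposals — a Gaussian
  approximation of the full conditional built from the current state, with
  the exact asymmetric acceptance correction.
* Latent fields (`xi`, `theta`, `Z*^(0)`, `Z^(1)`): single-site adaptive
  random-walk updates, vectorised over colour classes of the neighbour
  graph (non-adjacent areas have conditionally independent updates).
  Proposal scales adapt by Robbins-Monro only during burn-in.
* `Z*^(0)` additionally gets an independence refresh from its
  uncertainty-model prior each sweep (prior and proposal cancel, leaving a
  likelihood-only ratio); this breaks the slow coupling with the `f(Z)`
  coefficients.
* Two interweaving moves repair the classic hierarchical slow directions:
  a translation move `beta -> beta + delta`, `theta -> theta - W delta`
  (likelihood-invariant; `delta` has a conjugate Gaussian conditional), and
  a non-centred log-scale move for `(theta, sigma_theta)`.
* The ICAR imputation field is drawn exactly as a GMRF in the cached
  eigenbasis of the Laplacian; sum-to-zero is enforced by hard per-draw
  centring with a compensating intercept shift (recorded in the run
  manifest).
* Conjugate updates everywhere else (variances, `delta`, `gamma`, the
  Wishart precision).

Two chains by default; the `fast` profile (3,000 iterations, half burn-in)
is sized for tests and desk runs, the `paper` profile (100,000 iterations,
80,000 burn-in, thinning 10) mirrors the reference computation.
Convergence is assessed by the classic Gelman-Rubin factor on every
monitored quantity (threshold 1.1) plus arviz effective sample sizes on the
headline parameters; failure is reported, never silently accepted, and the
replication harness excludes non-converged replicates with a printed count.

## The synthetic-data generator

The generator emulates an urban areal study: a lattice of areas with 1.5 km
centroid spacing (25 x 25 spans ~51 km, comparable to a ward geography);
two independent Gaussian processes with exponential covariance
`sigma2 exp(-psi d)`, unit variance and a 20 km effective range (the
distance at which correlation drops to 0.05 is `-log(0.05)/psi`); a
measured confounder `C ~ N(zeta_1, 0.5)`; five latent confounders from a
Gaussian copula with fixed correlation matrix (three Gaussian margins — one
centred on the second spatial process — and Beta(12,12), Beta(6,14)
margins); exposure `X ~ N(0.3 C + M'(0.2, 0.3, 0.4, 0.1, 0.1), 0.25^2)`;
expected counts `E ~ U[15, 30]`; heterogeneity `theta ~ N(0, 0.05^2)`; and
Poisson counts with log-risk `0.2 X + 0.2 C + 0.2 sum_k M_k + theta`
(the nonlinear scenario adds `0.2 M_1^2 + 0.2 M_2^2`).  Surveys have 20
subjects per area, each drawn through the same copula with margins centred
on the area's latent values (unit variance for continuous, Bernoulli for
the Beta-derived).  Distribution scale parameters follow the `rnorm`
convention (second argument = standard deviation) throughout; with the
variance reading the generator cannot reproduce the reference study's
naive-model bias or interval widths, so the sd convention is the default
and both are exposed in `SimulationConfig`.

Sparsity designs delete the survey records of areas flagged by a logistic
missingness model: MAR `logit p = -0.4 + 0.6 X + 0.5 C`, MNAR
`logit p = -0.9 + 0.7 X + 0.7 C + 1.0 Z_true`.  Under these coefficients
the realised missing fraction is ~0.40 (MAR) and ~0.36 (MNAR) — the MNAR
fraction sits below one half because the score's mean (~0.08) does not
offset the -0.9 intercept; the tests therefore verify the MNAR fraction
against the plug-in logistic probabilities rather than a nominal one-half.

What the generator does *not* emulate: irregular administrative geographies
(centroid tables can supply one), varying survey sizes across areas
(supported by the models, not the default generator), covariate measurement
error, survey weights, and outcome-level spatial residual confounding
beyond what the spatially structured confounders induce.  Passing tests
show the method recovers a generating mechanism of exactly this form;
performance on real data depends on how far the survey and registry data
deviate from it.

## Problem sizes and reduced-scale checks

The reference simulation study used 625 areas and 100 replicates.  The
package's own acceptance checks run the same generating conditions at desk
scale: 400 areas / 10 replicates for the single-stage baselines (naive,
benchmark) and ~200 areas / 5-10 replicates for the two-stage fits, with the
`fast` MCMC profile.  At these sizes the single-stage averages reproduce
the reference values to a few hundredths; the two-stage averages carry
replicate noise of ~0.05 and a small residual attenuation (+0.03-0.05)
from the score-uncertainty model that shrinks with the number of in-sample
areas.  Coverage comparisons between complete-case and full-imputation
variants are reported but are noisy at single-digit replicate counts
(coverage granularity 1/R).

## Numerical details and degenerate inputs

* GP covariance gets `1e-8 sigma2` diagonal jitter before Cholesky.
* Neighbourhoods: distance cutoff defaulting to the smallest radius giving
  every area at least 4 neighbours, then per-area expansion to the nearest
  area so nobody is isolated; the relation is symmetrised.  Restriction to
  in-sample areas rebuilds neighbourhoods with the same rule.  If the graph
  still splits into components, `xi` columns are centred globally (a warning
  is issued) and the Wishart/ICAR degrees of freedom subtract one per
  component.
* A single area is rejected (no neighbour possible); empty centroid tables,
  duplicate ids and non-finite coordinates are errors.
* Spline bases are frozen from reference values (in-sample scores for
  `f`, covariates for `s_q`) before fitting: natural cubic with `df - 1`
  interior quantile knots, linear beyond the 1st/99th-percentile
  boundaries.  `f` defaults to quadratic; the recommended practice is to
  inspect the in-sample score/log-SMR shape and choose.
* Zero design-stage variance collapses `Z*^(0)` onto `Zhat^(0)` exactly
  (plug-in limit); variances are floored at 1e-12 to keep densities proper.
* The MNAR score coefficient `a_Z` is unidentifiable from data alone; both
  an `estimated` mode (N(0, 10) prior) and a `fixed(value)` sensitivity
  mode are provided, and evaluation runs fix it at the generating value.

## Known limitations

* The uncertainty model treats per-area score errors as independent; the
  shared component of design-stage error (coefficient uncertainty) is
  modelled as if independent, which leaves a small attenuation bias at
  small in-sample sizes.
* Separable MICAR dispersion only (one `Sigma_xi` for all areas);
  nonseparable multivariate CAR structures are out of scope.
* Categorical up-scaling (multinomial logit, `T - 1` latent columns) is
  implemented and unit-tested synthetically; the default study designs
  exercise only continuous and binary confounders.
* No survey weights; no feedback-allowing joint propensity estimation.
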