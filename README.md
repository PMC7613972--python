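# ecoeps

Unmeasured-confounding adjustment for area-referenced environmental-health
studies via a **generalized ecological propensity score (EPS)**, in a
two-stage sequential Bayesian framework, together with the full synthetic
simulation study used to validate it.

## The problem

Ecological (area-referenced) studies regress disease counts aggregated over
administrative areas on an area-level environmental exposure.  Registry data
rarely carry the behavioural and socio-economic confounders that individual
surveys measure, so the estimated exposure effect is often badly biased.
When a survey covers a *subset* of the areas, its subject-level measurements
can be up-scaled to latent area-level confounders and summarised in a single
continuous score that (i) balances the confounders with respect to a
continuous exposure given the measured covariates, and (ii) can be imputed
in the areas the survey never reached — under either a missing-at-random
(MAR) or a missing-not-at-random (MNAR) mechanism.

## The model

**Design stage** (in-sample areas `i = 1..S`, survey subjects `j = 1..J_i`,
confounders `k = 1..K`, mixed continuous/binary/categorical):

```
m_ijk  ~ ExpFam(M_ik)                 g_k(M_ik) = nu_k + xi_ik
xi_i | xi_s, Sigma_xi ~ N( mean_{s in ∂i} xi_s , Sigma_xi / n_i )   (MICAR)
Sigma_xi^-1 ~ Wishart_K(v, B),  v > K - 1,  sum-to-zero constraint on xi
X_i | C_i, M_i ~ N( delta_0 + C_i'delta_C + M_i'delta_M , sigma_X^2 )
Z_i^(0) := M_i'delta_M            (the generalized EPS, in-sample)
```

The neighbourhoods `∂i` are distance-based on area centroids (every area
keeps at least one neighbour).  The two submodels are one joint posterior:
areas with larger surveys get tighter scores, and the exposure data inform
the up-scaling.

**Analysis stage** (all areas `i = 1..N`), fitted jointly with no feedback
to the design stage:

```
Y_i ~ Poisson(E_i mu_i)
log mu_i = beta_0 + X_i beta_X + C_i'beta_C + f(Z_i) + theta_i
Z_i = Z*_i^(0)                    (i in-sample)   uncertainty model:
      Z*_i^(0) ~ N(Zhat_i^(0), sigma2hat_i)      (design-stage posterior)
Z_i = Z_i^(1)                     (i out-of-sample)  imputation model:
      Z_i ~ N(gamma_0 + X_i gamma_X + s_q(C_i) + phi_i, sigma_Z^2), phi ICAR
MNAR selection model:  ell_i ~ Bernoulli(pi_i),
      logit(pi_i) = a_0 + X_i a_X + C_i'a_C + Z_i a_Z
```

`f(Z)` is linear, quadratic or a natural cubic spline, chosen from the
in-sample score/log-SMR relationship.  Inference is Metropolis-within-Gibbs
(IWLS proposals for regression blocks, exact GMRF draws for the ICAR field,
conjugate variance updates, interweaving moves for the slow hierarchical
directions), with Gelman-Rubin and effective-sample-size diagnostics.

## Worked example

`python examples/two_stage_analysis.py` (100-area lattice, one simulated
replicate, generating exposure effect 0.20) prints:

```
design stage: corr(estimated score, generating score) = 0.987
mean posterior score variance = 0.0182

balancing check (association of X with each confounder):
confounder  partial_corr_given_C  partial_corr_given_C_Z0  attenuated
        M1                 0.771                   -0.010        True
        M2                 0.793                    0.002        True
        M3                 0.715                    0.020        True
        M4                 0.226                    0.026        True
        M5                 0.240                    0.006        True

analysis stage (generating exposure effect = 0.20):
  naive      beta_X = 0.801 (0.727 to 0.872); risk change per unit exposure = 122.9%
  benchmark  beta_X = 0.332 (0.104 to 0.559); risk change per unit exposure = 40.4%
  eps_mar    beta_X = 0.204 (-0.105 to 0.510); risk change per unit exposure = 24.1%
```

Reading it: the estimated score is conditionally balancing — given `C` and
`Z^(0)`, the exposure carries essentially no residual association with any
latent confounder (second column vs first).  The naive model inflates the
exposure effect four-fold (0.80 vs 0.20); adjusting with the score recovers
it, at the price of a wider interval that carries the design-stage
uncertainty.  Other examples: `simulate_dataset.py` (the generator),
`missingness_designs.py` (MAR/MNAR imputation), `replication_study.py`
(the metrics harness).  A thin CLI wraps the same calls:
`ecoeps simulate|design-stage|analyze|replicate --help`.

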