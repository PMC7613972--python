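"""Sparse survey coverage: score imputation under MAR and MNAR mechanisms.

Generates a dataset in which roughly 40% of areas lack survey records, fits
the design stage on the covered areas only, and imputes the score elsewhere
through the joint analysis-stage model (Gaussian imputation regression with
an ICAR spatial field; for MNAR, additionally a logistic selection model
with the score coefficient fixed at its generating value).
"""

import warnings

import numpy as np

from ecoeps import (
    MCMCSettings,
    MissingnessModelSpec,
    OutcomeModelSpec,
    SimulationConfig,
    build_lattice,
    fit_design_stage,
    fit_outcome_model,
    generate_dataset,
)

domain = build_lattice(13, 13)
mcmc = MCMCSettings(n_iter=4000, n_burnin=2000, seed=2)

for design, variant in [("MAR", "eps_mar"), ("MNAR", "eps_mnar")]:
    config = SimulationConfig(design=design, scenario="linear")
    eco, indiv = generate_dataset(domain, config, seed=99)
    miss = MissingnessModelSpec(a_Z_mode=("fixed", 1.0)) if design == "MNAR" else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dstage = fit_design_stage(indiv, eco, domain, mcmc=mcmc)
        res = fit_outcome_model(eco, dstage, domain, variant,
                                outcome=OutcomeModelSpec(f_spec="linear"),
                                missingness=miss, mcmc=mcmc)
    out_idx = np.flatnonzero(eco.ell == 1)
    r = np.corrcoef(res.Z_imputed["mean"], eco.Z_true[out_idx])[0, 1]
    s = res.beta_X_summary
    print(f"{design}: {eco.ell.sum()}/{eco.n_areas} areas missing; "
          f"corr(imputed score, truth) = {r:.2f}; "
          f"beta_X = {s['mean']:.3f} ({s['lower']:.3f} to {s['upper']:.3f})")
print("\nimputation recovers the score's spatial/covariate structure in the")
print("uncovered areas; intervals widen to reflect the imputation uncertainty")
print("(the generating exposure effect is 0.20; single small replicates are noisy)")
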