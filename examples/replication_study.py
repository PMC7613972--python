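"""A miniature replication study with the performance-metric harness.

Repeats (generate -> fit) over independent replicates for the naive and
benchmark models and prints the reference-style metrics table: averaged
posterior mean, mean bias (MB), RMSE, coverage of the nominal 95% interval,
and mean interval width against the generating value 0.20.  Scale it up
(more areas, more replicates, the `paper` MCMC profile) to approach the
published 625-area, 100-replicate study.
"""

from ecoeps import (
    MCMCSettings,
    SimulationConfig,
    build_lattice,
    compute_metrics,
    metrics_table,
    run_replications,
)

domain = build_lattice(12, 12)  # 144 areas for a quick run
config = SimulationConfig(design="full", scenario="linear")
results = run_replications(
    domain, config, ["naive", "benchmark"],
    mcmc=MCMCSettings(n_iter=3000, n_burnin=1500),
    n_replicates=5, seed=31,
)
metrics = [compute_metrics(results[v], config.beta_X_true)
           for v in ("naive", "benchmark")]
print(metrics_table(metrics).round(3).to_string(index=False))
print("\nnaive: large positive bias, zero coverage — the unmeasured")
print("confounders inflate the exposure effect; benchmark: unbiased with")
print("near-nominal coverage, the ceiling any adjustment can reach")
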