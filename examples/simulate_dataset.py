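"""Generate one synthetic area-referenced dataset and inspect its structure.

Builds a 100-area lattice geography, draws the full design-1 replicate
(spatial Gaussian processes, copula-linked mixed-type confounders, exposure,
Poisson counts, 20-subject surveys per area), and prints the quantities a
study of unmeasured confounding cares about.
"""

import numpy as np

from ecoeps import SimulationConfig, build_lattice, generate_dataset

domain = build_lattice(10, 10)  # 100 areas, 1.5 km spacing
config = SimulationConfig(design="full", scenario="linear")
eco, indiv = generate_dataset(domain, config, seed=42)

print(f"areas: {eco.n_areas}, survey records: {len(indiv.records)}")
print(f"expected counts E: mean {eco.E.mean():.1f}, range "
      f"[{eco.E.min():.1f}, {eco.E.max():.1f}]  (uniform on [15, 30])")
print(f"observed counts Y: mean {eco.Y.mean():.1f}, SMR mean {(eco.Y/eco.E).mean():.2f}")

# The confounding mechanism: exposure X and log-risk both load on the five
# latent confounders M, so their marginal association is inflated.
slope_naive = np.polyfit(eco.X, np.log((eco.Y + 0.5) / eco.E), 1)[0]
print(f"\ncrude log-SMR slope on X: {slope_naive:.2f}  "
      f"(generating exposure effect is {config.beta_X_true})")
print("the gap is residual confounding carried by M1..M5 through Z_true")
print(f"corr(X, Z_true) = {np.corrcoef(eco.X, eco.Z_true)[0, 1]:.2f}")

# Survey records are noisy per-subject measurements centred on the area truth.
bar = indiv.records.groupby("area_id")["m1"].mean().reindex(eco.area_ids)
print(f"\ncorr(area mean of m1 over 20 subjects, latent M1) = "
      f"{np.corrcoef(bar, eco.M_true[:, 0])[0, 1]:.2f}")
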