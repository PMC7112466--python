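"""Why the susceptibility chi overshoots the SIR threshold — and Delta doesn't.

Above the threshold the outbreak-size distribution is bimodal: early
die-outs at rho = 1/N plus a 'lump' of macroscopic outbreaks.  Truncating
the ensemble at a cutoff r_c (keeping only rho <= r_c) restores chi as a
threshold locator when the lump is excluded, and the chi peak drifts right
as more of the lump is admitted.  Collapsing the supercritical tail into a
point mass at r_c (the lump model) leaves the variability peak unmoved —
Delta measures the heterogeneity of the distribution, which is maximal at
the threshold wherever the lump sits.
"""

import numpy as np

import epithresh as et
from epithresh import CutoffConfig
from epithresh.distribution import lump_model_variability_curve

N, K = 3000, 10
lambda_c = 1 / (K - 1)
grid = np.linspace(0.06, 0.17, 31)

ensembles = et.run_ensemble(
    lambda seed: et.generate_rrn(N, K, seed),
    grid, mu=1.0, model="SIR", n_networks=5, n_runs=2000, master_seed=5)

print(f"HMF threshold lambda_c = {lambda_c:.4f}; grid step = "
      f"{grid[1] - grid[0]:.4f}\n")

print("truncated susceptibility: peak position vs cutoff r_c")
for rc in (0.05, 0.2, 0.4):
    chis = np.array([et.truncated_susceptibility(e, CutoffConfig(rc))
                     for e in ensembles])
    print(f"  r_c = {rc:4.2f}: lambda_pchi = {grid[int(np.nanargmax(chis))]:.4f}")
print("  (drifts right as the lump enters the sub-ensemble)\n")

print("lump-model variability: peak position vs lump location r_c")
dists = [et.empirical_distribution(e) for e in ensembles]
for rc in (0.05, 0.2, 0.4):
    curve = lump_model_variability_curve(grid, dists, CutoffConfig(rc),
                                         lambda_c=lambda_c)
    print(f"  r_c = {rc:4.2f}: lambda_pDelta = {grid[int(np.nanargmax(curve))]:.4f}")
print("  (identical: the variability peak ignores where the lump sits)")
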