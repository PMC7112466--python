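"""Locate the SIR epidemic threshold on a random regular network.

Generates RRN instances (N = 1000, k = 10), scans the effective
transmission rate lambda = beta/mu across a 31-point grid bracketing the
mean-field prediction 1/(k-1), and locates the peaks of the variability
Delta and the susceptibility chi.  The Delta peak sits at the threshold;
the chi peak overshoots it — the central observation this package exists
to quantify.
"""

import numpy as np

import epithresh as et

N, K = 1000, 10
lambda_hmf = 1 / (K - 1)
grid = np.linspace(0.06, 0.17, 31)

ensembles = et.run_ensemble(
    lambda seed: et.generate_rrn(N, K, seed),
    grid, mu=1.0, model="SIR", n_networks=5, n_runs=2000, master_seed=1)
scan = et.build_scan(ensembles)
peak_delta = et.find_peak(scan, "variability")
peak_chi = et.find_peak(scan, "susceptibility")

print(f"HMF prediction        lambda_c = 1/(k-1) = {lambda_hmf:.4f}")
print(f"variability peak      lambda_pDelta      = {peak_delta.lambda_peak:.4f}")
print(f"susceptibility peak   lambda_pchi        = {peak_chi.lambda_peak:.4f}")
print(f"grid step                                = {grid[1] - grid[0]:.4f}")
print()
print("lambda_pDelta should agree with 1/(k-1) to within one grid step,")
print("while lambda_pchi lands noticeably to its right: the supercritical")
print("'lump' of macroscopic outbreaks inflates chi above threshold.")
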