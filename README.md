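# epithresh

Numerical identification of epidemic thresholds for SIR (and SIS) dynamics
on finite-size networks.

## The problem

On a network, the discrete-time SIR model has a critical effective
transmission rate λ_c = β/μ (β the per-contact transmission probability, μ
the recovery probability) above which an outbreak reaches a finite fraction
of the population. Several theories predict λ_c from network structure —

| prediction | formula |
|---|---|
| heterogeneous mean-field (SIR) | λ_c = ⟨k⟩ / (⟨k²⟩ − ⟨k⟩) |
| heterogeneous mean-field (SIS) | λ_c = ⟨k⟩ / ⟨k²⟩ |
| quenched mean-field | λ_c = 1 / Λ_N (leading adjacency eigenvalue) |
| bond percolation (heterogeneous infectious periods) | λ_c = ⟨k⟩ / (⟨k²⟩ − 2⟨k⟩) |
| edge-based compartmental | λ_c(μ) = ⟨k⟩ / (⟨k²⟩ + (μ−2)⟨k⟩) |

— but checking them against simulation requires a *numerical* threshold
estimator. For SIS the standard tool is the susceptibility
χ = N(⟨ρ²⟩−⟨ρ⟩²)/⟨ρ⟩ of the order parameter ρ over realizations, whose peak
over λ marks the transition. For SIR, however, χ systematically overshoots:
above threshold the outbreak-size distribution is bimodal (early die-outs at
ρ = 1/N plus a "lump" of macroscopic outbreaks), and the lump keeps
inflating the variance well past λ_c. The **variability**

Δ = √(⟨ρ²⟩ − ⟨ρ⟩²) / ⟨ρ⟩

— the relative standard deviation of the outbreak size — measures the
*heterogeneity* of the distribution instead, which is maximal at the
threshold; its peak position λ_pΔ is a reliable SIR threshold estimate and
works for SIS too. This package implements the whole workflow: network
generation (random regular, configuration-model scale-free with structural
or natural degree cutoffs, empirical edge lists), fast stochastic SIR/SIS
simulation over λ grids, the Δ/χ estimators and peak extraction, all five
closed-form predictions, and the outbreak-size-distribution diagnostics
(critical power-law exponent, bimodality, cutoff hypothesis, lump model)
that explain why Δ works where χ fails.

## Worked example

```python
import numpy as np
import epithresh as et

grid = np.linspace(0.06, 0.17, 31)          # brackets 1/(k-1) = 1/9
ens = et.run_ensemble(lambda seed: et.generate_rrn(1000, 10, seed),
                      grid, mu=1.0, model="SIR",
                      n_networks=5, n_runs=2000, master_seed=1)
scan = et.build_scan(ens)
print(et.find_peak(scan, "variability").lambda_peak)      # 0.1077
print(et.find_peak(scan, "susceptibility").lambda_peak)   # 0.1407
```

The variability peak lands within one grid step (0.0037) of the mean-field
threshold 1/9 ≈ 0.1111, while the susceptibility peak overshoots by ~27% —
the SIR bias the variability measure was introduced to avoid. The narrative
scripts in `examples/` walk through each capability (threshold scans, the
outbreak-size distribution across the transition, the cutoff/lump analysis,
scale-free and SIS variants, the exact small-graph percolation oracle); for
instance `python examples/threshold_scan_rrn.py` prints

```
HMF prediction        lambda_c = 1/(k-1) = 0.1111
variability peak      lambda_pDelta      = 0.1077
susceptibility peak   lambda_pchi        = 0.1407
grid step                                = 0.0037
```

A thin CLI mirrors the library (`epithresh net`, `scan`, `theory`, `peak`,
`dist`, `run`, `report`); `epithresh run config.yaml` executes a fully
seeded experiment and writes the scan TSV, peak JSON and a comparison-table
row (N, k_max, assortativity r, HMF/QMF predictions, numerical thresholds).

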