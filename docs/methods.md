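# Methods

## Dynamics

Both models run in discrete time with synchronous updates (Δt = 1). At each
step, every susceptible node with `n_i` currently infected neighbors becomes
infected with probability `1 − (1 − β)^{n_i}` — realised as one independent
Bernoulli(β) trial per infected neighbor, which is the same law. Every node
that was infected at the *start* of the step then recovers with probability
μ (SIR: permanently removed; SIS: susceptible again). A node infected at
step t therefore transmits for the first time at step t+1 and can recover at
the end of t+1 at the earliest. This ordering is load-bearing: with μ = 1
each edge incident to an ever-infected node is "used" exactly once with
success probability β, so an SIR realization is precisely one sample of bond
percolation with occupation probability β, and the final recovered set is
the seed's percolation cluster. The 2^E enumeration in
`distribution.exact_final_size_distribution` is consequently an *exact*
oracle for the simulator on small graphs, not an approximation; the test
suite verifies total-variation agreement on every connected graph with ≤ 5
nodes.

Each realization starts from a single uniformly random seed node. SIR runs
to absorption (no infected left). λ grids are scanned by varying β at fixed
μ (β = λμ ≤ 1).

### SIS stationary measurement

SIS has an absorbing state, so on a finite network the true stationary
density is 0 and some convention is needed. A run is given a step budget
`t_max`; if it survives, the infected density is averaged over the final
`t_window` steps. The ensemble statistic is **conditioned on survival**:
absorbed runs contribute no density observation (their count is retained in
the ensemble's `survived` bookkeeping). We initially evaluated the simpler
convention of entering absorbed runs as 0; it makes Δ = σ/mean diverge as
the survival probability vanishes, which pins the variability peak to the
leftmost grid point with any survivor — an artifact of the convention, not a
property of the transition — and pushes the Δ and χ peaks two grid ranges
apart. Conditioning on survival (the spirit of quasi-stationary analysis,
without its reweighting machinery) restores the expected behavior: both
peaks coincide near the mean-field threshold. Desk-scale defaults in the
tests are t_max = 300 and t_window = 100 on N = 10³ networks, large enough
that surviving runs have relaxed; the full-scale defaults (t_max = 10⁴,
t_window = 10³) remain the library defaults.

## Estimators

For the ensemble {ρ_i} at one λ:

* variability Δ = √(⟨ρ²⟩ − ⟨ρ⟩²) / ⟨ρ⟩,
* susceptibility χ = N (⟨ρ²⟩ − ⟨ρ⟩²) / ⟨ρ⟩.

Moments are plug-in (population, 1/n) moments: both quantities are defined
through ensemble moments, the n vs n−1 distinction is negligible at the
realization counts used (≥ 10³), and the identity χ = N Δ² ⟨ρ⟩ then holds to
machine precision (fuzz-tested). The numerical threshold is the discrete
grid argmax of the measure — no interpolation or smoothing by default, so
the estimate carries no untracked bias; a 3-point quadratic refinement is
available behind a flag. Ties break toward the smallest λ; an argmax at a
grid endpoint raises a warning (scan range too narrow) rather than an error,
because on strongly disassortative empirical networks the predictions used
to anchor the grid can miss badly. When a mean-field anchor exists, the
default grid is 31 uniform points on [0.5, 2.0] × anchor.

## Outbreak-size distribution diagnostics

`empirical_distribution` places relative frequencies on the exact support
{1/N, …, 1}. Log-binned views use the *average mass per lattice site* in a
bin rather than mass divided by geometric bin width: near ρ = 1/N bins are
narrower than the lattice spacing 1/N, and width-normalisation there
systematically steepens slopes (an extra ρ^(−1) factor), while
per-site averaging stays unbiased on lattice-supported data.

* **Power-law exponent.** Least-squares slope of log density vs log ρ over
  logarithmically binned masses (20 bins/decade by default) in a
  caller-chosen fit range; the range must exclude the supercritical lump,
  and at the threshold on RRN (k = 10) the fit over ρ ∈ [1/N, 0.01]
  reproduces the critical branching-process value α ≈ −3/2. A graphical
  slope estimator, not an MLE, is used deliberately: the quantity of
  interest is the visible slope of a distribution with an upper cutoff.
* **Mode detection.** Local maxima of the log-binned mass density with
  plateau merging; boundary bins may be modes. Modes carrying less than
  `min_mass` total probability (default 10⁻³) are discarded — in a sparse
  Monte-Carlo tail an isolated single-count bin flanked by empty bins would
  otherwise register as a mode. A mode's location is the mass-weighted mean
  of its plateau's bin centers.
* **Cutoff hypothesis.** `truncated_susceptibility` recomputes χ on the
  sub-ensemble {ρ ≤ r_c} with the original N. With r_c below the lump the χ
  peak returns to the threshold; admitting more of the lump (r_c = 0.2, 0.4)
  drags it right. The inequality conventions follow the construction being
  modelled exactly: truncation keeps ρ ≤ r_c, while the lump weight sums
  mass *strictly below* r_c.
* **Lump model.** `lumped_variability` evaluates Δ on a modified
  distribution: mass below r_c kept, all remaining probability concentrated
  at r_c. `lump_model_variability_curve` assembles the Δ(λ) curve for a
  scan, imposing the lump only at grid points strictly above the one
  identified with λ_c. The gating is part of the model's meaning: the lump
  is a feature of strictly supercritical distributions, and at the threshold
  itself the distribution is a pure power law with cutoff, so collapsing its
  tail there would model a feature that does not exist. Ungated, the
  smallest cutoff (r_c = 0.05) clips genuine critical fluctuation mass in
  ρ ∈ [r_c, ~0.3] and shifts its peak one grid step (~3%) left; with the
  gating the peak position is invariant to r_c, which is the point of the
  construction — the variability peak does not track the lump location,
  whereas the susceptibility peak does.

## Network generation

* **RRN**: networkx's stub-pairing random regular graph; exact regularity is
  asserted by construction, and ⟨k²⟩ = k² makes every closed-form threshold
  exact for comparison.
* **SFN**: configuration model on a degree sequence drawn by inverse-CDF
  sampling from the exactly normalised discrete law P(k) ∝ k^(−γ) on
  [k_min, cap], with one entry resampled while the stub sum is odd. The cap
  is ⌊N^(1/2)⌋ (structural cutoff) or ⌊N^(1/(γ−1))⌋ (natural cutoff). The
  stub multigraph is simplified by erasure (self-loops removed, multi-edges
  collapsed), with the erased count logged; erasure perturbs only the
  largest degrees, by O(k_max²/N) edges in expectation. k_min defaults to 3
  so the giant component dominates for γ ≤ 3.5 and ⟨ρ⟩(λ) stays smooth.
  Under the structural cutoff degree correlations vanish (r ≈ 0); under the
  natural cutoff with γ < 3 the graph is measurably disassortative (r < 0)
  — both verified in the tests, since this contrast drives the HMF/QMF
  disagreement on heavy-tailed graphs.
* **Edge lists**: whitespace-separated integer pairs, `#` comments;
  self-loops and duplicates dropped with a logged count; arbitrary labels
  compacted to 0..N−1 in first-appearance order (identity if already
  canonical, so write→read round-trips exactly). Real networks are analysed
  as-is — no silent giant-component extraction; a warning reports the
  giant-component fraction when it is below 1.

Thresholds are always evaluated on the *realized* degree sequence (and
adjacency spectrum) of the instance at hand, not the nominal ensemble law,
so finite-size comparisons are like-for-like. The leading adjacency
eigenvalue comes from sparse Lanczos iteration (tol 10⁻⁸, ≤ 10⁴
iterations); the matrix is never densified.

## Seeding and determinism

`run_ensemble` derives the substream of realization (i_λ, i_network, i_run)
from the master seed and those indices alone (numpy `SeedSequence` with
positional spawn keys; per-run 31-bit seeds feed the numba kernels), so
results are bit-identical regardless of execution order or batching, and an
experiment config plus the package version pins every output byte.

## What the synthetic generators do and do not emulate

The RRN/SFN ensembles reproduce the degree structure the closed-form
theories are parameterised by — constant degree, power-law tails with
controlled cutoffs, the presence or absence of degree-degree correlations.
They do not emulate clustering, community structure, spatial embedding, or
degree correlations beyond those the cutoff convention induces; passing
tests therefore validate the estimators and the theory formulas under the
stated degree structure, not the accuracy of any mean-field prediction on
real-world networks, where the package's own comparison table (HMF vs QMF
vs λ_pΔ, keyed by assortativity) is the intended instrument.

## Problem sizes in the test suite

Scan-level checks use 31-point λ grids with 2×10⁴ realizations per point on
RRN N ∈ {10³, 3×10³} (peak location/stability) and N = 10⁴ (cutoff/lump
analysis), 10⁵ realizations for the critical exponent, 3×10⁴ for
bimodality, and 10⁵ runs per (graph, β) pair in the oracle-equivalence
property; SIS consistency uses N = 10³ with 10³ runs per point. These sizes
resolve peak positions to one grid step and exponents to ±0.1, which is the
resolution the scientific claims are made at.

## Known limitations

* No continuous-time (Gillespie) or asynchronous dynamics; with Δt = 1 the
  μ < 1 model has geometric infectious periods.
* SIS measurement is windowed-survival, not full quasi-stationary
  reweighting; near-threshold SIS peak *heights* are therefore
  protocol-dependent (positions are robust).
* No finite-size-scaling extrapolation λ_p(N → ∞) and no lifetime-based
  estimators.
* The exact final-size oracle enumerates 2^E configurations and refuses
  graphs with more than 20 edges.
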