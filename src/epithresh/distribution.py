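"""Outbreak-size distribution analysis.

Near the epidemic threshold the distribution P(rho) of final outbreak
fractions is strongly heterogeneous: subcritical ensembles decay roughly
exponentially, critical ones follow a power law P(rho) ~ rho^alpha with
alpha close to -3/2 (the mean-field branching-process exponent), and
supercritical ones are bimodal — a peak of early die-outs at rho = 1/N plus
a concentrated "lump" of macroscopic outbreaks.  The routines here quantify
each regime and probe how the lump corrupts the susceptibility-based
threshold estimate while leaving the variability-based one intact:

* ``truncated_susceptibility`` recomputes chi using only outbreaks with
  rho <= r_c (the cutoff hypothesis);
* ``lumped_variability`` recomputes Delta from a distribution whose mass at
  or above r_c is collapsed into a single point mass at r_c (the lump
  model).

``exact_final_size_distribution`` enumerates all 2^E bond-percolation edge
configurations of a small graph; for unit recovery probability (mu = 1) the
SIR final recovered set is exactly the seed's percolation cluster, so the
enumeration is an exact oracle for the Monte-Carlo dynamics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .epidemic import OutbreakEnsemble
from .estimators import _delta_chi
from .exceptions import InvalidParameterError
from .netgen import Network

__all__ = [
    "OutbreakDistribution",
    "CutoffConfig",
    "PowerLawFit",
    "empirical_distribution",
    "exact_final_size_distribution",
    "fit_powerlaw_exponent",
    "truncated_susceptibility",
    "lumped_variability",
    "lump_model_variability_curve",
    "detect_modes",
    "log_binned_density",
]

_NORM_TOL = 1e-12
_MAX_ENUM_EDGES = 20


@dataclass
class OutbreakDistribution:
    """Probability mass over the outbreak-size support {1/N, 2/N, ..., 1}.

    ``mass[m - 1]`` is P(rho = m / N).  Masses are non-negative and sum to 1.
    """

    n_nodes: int
    mass: np.ndarray

    def __post_init__(self):
        self.mass = np.asarray(self.mass, dtype=float)
        if self.mass.size != self.n_nodes:
            raise InvalidParameterError(
                f"mass must have length N = {self.n_nodes}, got {self.mass.size}")
        if np.any(self.mass < -_NORM_TOL):
            raise InvalidParameterError("negative probability mass")
        total = self.mass.sum()
        if abs(total - 1.0) > 1e-9:
            raise InvalidParameterError(f"masses sum to {total}, not 1")

    @property
    def support(self) -> np.ndarray:
        """Outbreak fractions m / N for m = 1..N."""
        return np.arange(1, self.n_nodes + 1) / self.n_nodes

    def moments(self) -> tuple[float, float]:
        rho = self.support
        return float((self.mass * rho).sum()), float((self.mass * rho ** 2).sum())

    def variability(self) -> float:
        m1, m2 = self.moments()
        if m1 == 0.0:
            return float("nan")
        return float(np.sqrt(max(m2 - m1 * m1, 0.0)) / m1)


@dataclass(frozen=True)
class CutoffConfig:
    """Outbreak-size cutoff fraction r_c used by the cutoff hypothesis and
    the lump model; must be at least one node's worth of outbreak."""

    r_c: float

    def validate(self, n_nodes: int) -> None:
        if not 0.0 < self.r_c <= 1.0:
            raise InvalidParameterError(f"r_c must lie in (0, 1], got {self.r_c}")
        if self.r_c < 1.0 / n_nodes:
            raise InvalidParameterError(
                f"r_c = {self.r_c} is below the minimum outbreak 1/N = {1.0 / n_nodes}")


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares slope of log P(rho) vs log rho over log-binned masses."""

    alpha: float
    fit_range: tuple[float, float]
    n_bins_used: int
    residual_rms: float


def empirical_distribution(ensemble: OutbreakEnsemble) -> OutbreakDistribution:
    """Relative frequencies of the outbreak sizes on the exact support."""
    values = np.asarray(ensemble.values, dtype=float)
    if values.size == 0:
        raise InvalidParameterError("empty ensemble")
    n = ensemble.n_nodes
    counts = np.bincount(
        np.clip(np.rint(values * n).astype(int), 1, n) - 1, minlength=n)
    return OutbreakDistribution(n_nodes=n, mass=counts / counts.sum())


def exact_final_size_distribution(network: Network, beta: float) -> OutbreakDistribution:
    """Exact final-size distribution for unit-recovery SIR, by brute-force
    bond-percolation enumeration.

    Each of the 2^E edge-occupation configurations (occupation probability
    ``beta`` per edge) is weighted by its probability; within a
    configuration, a uniformly chosen seed's outbreak is its connected
    cluster.  Refuses graphs with more than 20 edges.
    """
    if not 0.0 <= beta <= 1.0:
        raise InvalidParameterError(f"beta must be in [0, 1], got {beta}")
    m = network.n_edges
    if m > _MAX_ENUM_EDGES:
        raise InvalidParameterError(
            f"exact enumeration needs <= {_MAX_ENUM_EDGES} edges, got {m} "
            "(use Monte-Carlo for larger graphs)")
    n = network.n_nodes
    edges = network.edge_array
    mass = np.zeros(n)
    for occupied in itertools.product((False, True), repeat=m):
        k = sum(occupied)
        weight = (beta ** k) * ((1.0 - beta) ** (m - k))
        if weight == 0.0:
            continue
        # union-find over occupied edges
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for e, occ in enumerate(occupied):
            if occ:
                ra, rb = find(int(edges[e, 0])), find(int(edges[e, 1]))
                if ra != rb:
                    parent[ra] = rb
        sizes = np.bincount([find(i) for i in range(n)], minlength=n)
        # seed uniform over nodes: P(cluster size = s) = (# nodes in s-clusters)/N
        for s in sizes[sizes > 0]:
            mass[s - 1] += weight * s / n
    return OutbreakDistribution(n_nodes=n, mass=mass / mass.sum())


def log_binned_density(dist: OutbreakDistribution, n_bins: int,
                       lo: float | None = None, hi: float | None = None):
    """Log-bin a discrete outbreak-size distribution.

    Returns ``(centers, density, bin_mass)`` over the bins that contain at
    least one support point.  Because the support is the integer lattice
    m/N, the density in a bin is the *average mass per support point* in
    that bin (total mass / number of lattice points), which is the estimator
    that stays unbiased when bins near 1/N are narrower than the lattice
    spacing; centers are the geometric means of the lattice points covered.
    """
    if n_bins < 2:
        raise InvalidParameterError("need at least 2 bins")
    rho = dist.support
    lo = 1.0 / dist.n_nodes if lo is None else lo
    hi = 1.0 if hi is None else hi
    if not 0 < lo < hi <= 1.0:
        raise InvalidParameterError(f"bad bin range [{lo}, {hi}]")
    edges = np.geomspace(lo * (1 - 1e-12), hi * (1 + 1e-12), n_bins + 1)
    which = np.digitize(rho, edges) - 1
    in_range = (which >= 0) & (which < n_bins)
    centers, density, bin_mass = [], [], []
    for b in range(n_bins):
        sites = np.where(in_range & (which == b))[0]
        if sites.size == 0:
            continue
        total = dist.mass[sites].sum()
        centers.append(float(np.exp(np.log(rho[sites]).mean())))
        density.append(float(total / sites.size))
        bin_mass.append(float(total))
    return np.array(centers), np.array(density), np.array(bin_mass)


def fit_powerlaw_exponent(dist: OutbreakDistribution,
                          fit_range: tuple[float, float],
                          bins_per_decade: int = 20) -> PowerLawFit:
    """Fit P(rho) ~ rho^alpha by least squares on log-binned masses.

    The fit range must be chosen by the caller to exclude the supercritical
    lump; requires at least 5 occupied bins with positive mass.
    """
    lo, hi = fit_range
    if not 0 < lo < hi <= 1.0:
        raise InvalidParameterError(f"bad fit range {fit_range}")
    n_decades = np.log10(hi / lo)
    n_bins = max(int(np.ceil(bins_per_decade * n_decades)), 2)
    centers, density, _ = log_binned_density(dist, n_bins, lo=lo, hi=hi)
    keep = density > 0
    if keep.sum() < 5:
        raise InvalidParameterError(
            f"only {int(keep.sum())} occupied bins with positive mass in "
            f"{fit_range}; need >= 5 for a slope fit")
    x = np.log10(centers[keep])
    y = np.log10(density[keep])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return PowerLawFit(alpha=float(slope), fit_range=(lo, hi),
                       n_bins_used=int(keep.sum()),
                       residual_rms=float(np.sqrt(np.mean(resid ** 2))))


def truncated_susceptibility(ensemble: OutbreakEnsemble,
                             cutoff: CutoffConfig) -> float:
    """chi of the sub-ensemble {rho : rho <= r_c}, keeping the original N.

    This is the cutoff hypothesis: discarding the supercritical lump
    (r_c small enough) restores chi as a threshold locator.
    """
    cutoff.validate(ensemble.n_nodes)
    values = ensemble.values[ensemble.values <= cutoff.r_c + _NORM_TOL]
    if values.size == 0:
        raise InvalidParameterError(
            f"no outbreak sizes at or below r_c = {cutoff.r_c}")
    return _delta_chi(values, ensemble.n_nodes)[1]


def lumped_variability(dist: OutbreakDistribution, cutoff: CutoffConfig) -> float:
    """Delta of the lump-model distribution: masses for rho < r_c are kept
    and all remaining probability is concentrated as a point mass at r_c.

    Note the strict inequality: mass exactly at r_c is part of the lump.
    """
    cutoff.validate(dist.n_nodes)
    n = dist.n_nodes
    rho = dist.support
    below = rho < cutoff.r_c - _NORM_TOL
    lump_weight = 1.0 - dist.mass[below].sum()
    m1 = float((dist.mass[below] * rho[below]).sum() + lump_weight * cutoff.r_c)
    m2 = float((dist.mass[below] * rho[below] ** 2).sum()
               + lump_weight * cutoff.r_c ** 2)
    if m1 == 0.0:
        return float("nan")
    return float(np.sqrt(max(m2 - m1 * m1, 0.0)) / m1)


def lump_model_variability_curve(lambdas, dists, cutoff: CutoffConfig,
                                 lambda_c: float) -> np.ndarray:
    """Variability-vs-lambda curve under the lump model.

    The lump is a feature of *strictly supercritical* outbreak-size
    distributions: below and at the threshold there are no macroscopic
    outbreaks to collapse, and the distribution is exponential or a pure
    power law with cutoff.  Accordingly, grid points up to and including the
    one nearest ``lambda_c`` keep the plain variability of their
    distribution, while points above it use :func:`lumped_variability`.

    Scanning this curve for different cutoff fractions r_c probes the
    robustness of the variability peak: unlike the susceptibility under the
    cutoff hypothesis, its position does not track the lump location.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size != len(dists):
        raise InvalidParameterError("lambdas and dists must have equal length")
    idx_c = int(np.argmin(np.abs(lambdas - lambda_c)))
    out = np.empty(lambdas.size)
    for i, d in enumerate(dists):
        out[i] = d.variability() if i <= idx_c else lumped_variability(d, cutoff)
    return out


def detect_modes(dist: OutbreakDistribution, log_bins: int = 40,
                 min_mass: float = 1e-3) -> list[float]:
    """Local maxima of the log-binned mass density, sorted by location.

    Plateaus of equal density are merged into a single mode; the first and
    last occupied bins may be modes.  Modes carrying less than ``min_mass``
    total probability are discarded as sampling noise (isolated single-count
    bins in a sparse tail would otherwise register as maxima).  Each mode's
    location is the mass-weighted mean outbreak fraction over its plateau.
    """
    if log_bins < 10:
        raise InvalidParameterError("log_bins must be >= 10")
    centers, density, bin_mass = log_binned_density(dist, log_bins)
    k = centers.size
    if k == 0:
        raise InvalidParameterError("distribution has no support")
    if k == 1:
        return [float(centers[0])]
    modes: list[float] = []
    i = 0
    while i < k:
        j = i
        while j + 1 < k and density[j + 1] == density[i]:
            j += 1  # plateau
        left_ok = i == 0 or density[i - 1] < density[i]
        right_ok = j == k - 1 or density[j + 1] < density[i]
        if left_ok and right_ok:
            weight = bin_mass[i:j + 1].sum()
            if weight >= min_mass:
                loc = float((centers[i:j + 1] * bin_mass[i:j + 1]).sum() / weight)
                modes.append(loc)
        i = j + 1
    if not modes:
        # strictly monotone densities still have an argmax
        b = int(np.argmax(density))
        modes = [float(centers[b])]
    return sorted(modes)
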