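"""Discrete-time stochastic SIR and SIS dynamics and ensemble runners.

The dynamics: starting from a single randomly chosen infected seed, at each
time step every susceptible node with ``n_i`` infected neighbors becomes
infected with probability ``1 - (1 - beta)**n_i``, and every node infected at
the start of the step recovers (SIR: permanently; SIS: back to susceptible)
with probability ``mu``.  The effective transmission rate is
``lambda = beta / mu``; scans vary ``beta`` at fixed ``mu``.

With ``mu = 1`` an SIR realization is exactly one sample of bond percolation
with occupation probability ``beta`` — the final recovered set is the seed's
percolation cluster — which is what makes the small-graph enumeration in
:mod:`epithresh.distribution` an exact oracle for these dynamics.
"""

from __future__ import annotations

from collections.abc import Callable, Sequence
from dataclasses import dataclass, field

import numpy as np

from ._kernels import sir_final_sizes, sis_runs
from .exceptions import InvalidParameterError
from .netgen import Network

__all__ = [
    "EpidemicConfig",
    "SimResult",
    "OutbreakEnsemble",
    "simulate_sir",
    "simulate_sis",
    "run_ensemble",
    "DEFAULT_T_MAX",
    "DEFAULT_T_WINDOW",
]

#: Default SIS step budget and stationary averaging window.
DEFAULT_T_MAX = 10_000
DEFAULT_T_WINDOW = 1_000

_SEED_MOD = 2 ** 31


@dataclass(frozen=True)
class EpidemicConfig:
    """Validated epidemic parameters.

    ``lambda_`` is the effective transmission rate lambda = beta / mu; the
    per-contact transmission probability beta = lambda * mu must not exceed 1.
    """

    model: str
    mu: float
    lambda_: float
    t_max: int = DEFAULT_T_MAX
    t_window: int = DEFAULT_T_WINDOW

    def __post_init__(self):
        if self.model not in ("SIR", "SIS"):
            raise InvalidParameterError(f"model must be SIR or SIS, got {self.model!r}")
        if not 0.0 < self.mu <= 1.0:
            raise InvalidParameterError(f"mu must be in (0, 1], got {self.mu}")
        if self.lambda_ < 0:
            raise InvalidParameterError("lambda must be non-negative")
        if self.beta > 1.0:
            raise InvalidParameterError(
                f"beta = lambda * mu = {self.beta:.4g} exceeds 1 (lambda={self.lambda_})")
        if self.model == "SIS" and not self.t_window < self.t_max:
            raise InvalidParameterError("t_window must be smaller than t_max")

    @property
    def beta(self) -> float:
        return self.lambda_ * self.mu


@dataclass(frozen=True)
class SimResult:
    """Outcome of a single realization.

    ``final_fraction`` is the recovered fraction at absorption for SIR
    (always >= 1/N: the seed ends recovered) or the stationary infected
    density estimate for SIS.  ``survived`` is meaningful for SIS only and
    flags a run that reached ``t_max`` without absorption.
    """

    final_fraction: float
    duration: int
    survived: bool = True


@dataclass
class OutbreakEnsemble:
    """All outbreak observations collected at one transmission rate.

    For SIR, ``values`` holds the final recovered fraction of every
    realization (``n_networks * n_runs_per_network`` entries).  For SIS the
    observable is the stationary infected density, which exists only on
    survival: ``values`` holds the densities of the surviving runs and
    ``survived`` the per-realization survival flags over all
    ``n_networks * n_runs_per_network`` attempts.
    """

    lambda_: float
    n_nodes: int
    values: np.ndarray
    n_networks: int = 1
    n_runs_per_network: int = 0
    survived: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.n_runs_per_network == 0 and self.n_networks:
            self.n_runs_per_network = self.values.size // self.n_networks

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def survival_fraction(self) -> float:
        if self.survived is None:
            return 1.0
        return float(self.survived.mean()) if self.survived.size else 0.0


def _check_sir_params(beta, mu):
    if not 0.0 <= beta <= 1.0:
        raise InvalidParameterError(f"beta must be in [0, 1], got {beta}")
    if not 0.0 < mu <= 1.0:
        raise InvalidParameterError(f"mu must be in (0, 1], got {mu}")


def _as_seed_array(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, _SEED_MOD, size=n, dtype=np.int64)


def simulate_sir(network: Network, beta: float, mu: float, seed_node: int,
                 rng: np.random.Generator) -> SimResult:
    """One SIR realization from ``seed_node``; returns the final recovered
    fraction and the number of steps to absorption."""
    _check_sir_params(beta, mu)
    if not 0 <= seed_node < network.n_nodes:
        raise InvalidParameterError(f"seed_node {seed_node} outside 0..N-1")
    sizes = np.empty(1)
    durations = np.empty(1, dtype=np.int64)
    sir_final_sizes(network.indptr, network.indices, float(beta), float(mu),
                    _as_seed_array(rng, 1),
                    np.array([seed_node], dtype=np.int64), sizes, durations)
    return SimResult(final_fraction=float(sizes[0]), duration=int(durations[0]))


def simulate_sis(network: Network, beta: float, mu: float, seed_node: int,
                 rng: np.random.Generator, t_max: int = DEFAULT_T_MAX,
                 t_window: int = DEFAULT_T_WINDOW) -> SimResult:
    """One SIS realization; returns the infected density averaged over the
    final ``t_window`` steps if the run survives to ``t_max``, else 0."""
    _check_sir_params(beta, mu)
    if not 0 <= seed_node < network.n_nodes:
        raise InvalidParameterError(f"seed_node {seed_node} outside 0..N-1")
    if not t_window < t_max:
        raise InvalidParameterError("t_window must be smaller than t_max")
    density = np.empty(1)
    survived = np.empty(1, dtype=np.int64)
    durations = np.empty(1, dtype=np.int64)
    sis_runs(network.indptr, network.indices, float(beta), float(mu),
             int(t_max), int(t_window), _as_seed_array(rng, 1),
             np.array([seed_node], dtype=np.int64), density, survived, durations)
    return SimResult(final_fraction=float(density[0]), duration=int(durations[0]),
                     survived=bool(survived[0]))


def _sir_batch(network, beta, mu, seeds, seed_nodes):
    sizes = np.empty(seeds.size)
    durations = np.empty(seeds.size, dtype=np.int64)
    sir_final_sizes(network.indptr, network.indices, float(beta), float(mu),
                    seeds, seed_nodes, sizes, durations)
    return sizes, None


def _sis_batch(network, beta, mu, seeds, seed_nodes, t_max, t_window):
    density = np.empty(seeds.size)
    survived = np.empty(seeds.size, dtype=np.int64)
    durations = np.empty(seeds.size, dtype=np.int64)
    sis_runs(network.indptr, network.indices, float(beta), float(mu),
             int(t_max), int(t_window), seeds, seed_nodes,
             density, survived, durations)
    return density, survived


NetworkSource = Network | Callable[[int], Network]


def run_ensemble(network_source: NetworkSource,
                 lambda_grid: Sequence[float],
                 mu: float,
                 model: str = "SIR",
                 n_networks: int = 1,
                 n_runs: int = 1000,
                 master_seed: int = 0,
                 t_max: int = DEFAULT_T_MAX,
                 t_window: int = DEFAULT_T_WINDOW) -> list[OutbreakEnsemble]:
    """Scan a lambda grid: for each rate, run ``n_runs`` realizations on each
    of ``n_networks`` networks with uniformly random seed nodes.

    ``network_source`` is either a fixed :class:`Network` (reused for every
    realization; ``n_networks`` must be 1) or a callable ``seed -> Network``
    drawing a fresh instance.  The same ``n_networks`` network instances are
    shared across the whole grid.

    Seeding is position-based: the substream of realization ``(i_lambda,
    i_network, i_run)`` is a pure function of ``master_seed`` and those
    indices, so results are bit-identical regardless of execution order.
    """
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if model not in ("SIR", "SIS"):
        raise InvalidParameterError(f"model must be SIR or SIS, got {model!r}")
    for lam in lambda_grid:
        if lam * mu > 1.0 + 1e-12:
            raise InvalidParameterError(
                f"lambda = {lam:.6g} gives beta = lambda * mu = {lam * mu:.6g} > 1")
    if isinstance(network_source, Network):
        if n_networks != 1:
            raise InvalidParameterError(
                "a fixed network requires n_networks = 1")
        networks = [network_source]
    else:
        networks = []
        for ni in range(n_networks):
            net_seed = int(np.random.SeedSequence(
                entropy=master_seed, spawn_key=(0, ni)).generate_state(1)[0] % _SEED_MOD)
            networks.append(network_source(net_seed))
    n_nodes = networks[0].n_nodes
    if any(net.n_nodes != n_nodes for net in networks):
        raise InvalidParameterError("all networks in an ensemble must share N")

    ensembles = []
    for li, lam in enumerate(lambda_grid):
        beta = float(lam * mu)
        values = np.empty(n_networks * n_runs)
        survived = np.empty(n_networks * n_runs, dtype=np.int64) if model == "SIS" else None
        for ni, net in enumerate(networks):
            ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(1, li, ni))
            run_rng = np.random.default_rng(ss)
            seeds = _as_seed_array(run_rng, n_runs)
            seed_nodes = run_rng.integers(0, n_nodes, size=n_runs, dtype=np.int64)
            if model == "SIR":
                vals, surv = _sir_batch(net, beta, mu, seeds, seed_nodes)
            else:
                vals, surv = _sis_batch(net, beta, mu, seeds, seed_nodes,
                                        t_max, t_window)
            values[ni * n_runs:(ni + 1) * n_runs] = vals
            if surv is not None:
                survived[ni * n_runs:(ni + 1) * n_runs] = surv
        if model == "SIS":
            # the stationary density is defined conditional on survival;
            # absorbed runs carry no observation (their count is kept in
            # `survived` for bookkeeping)
            values = values[survived == 1]
        ensembles.append(OutbreakEnsemble(
            lambda_=float(lam), n_nodes=n_nodes, values=values,
            n_networks=n_networks, n_runs_per_network=n_runs, survived=survived))
    return ensembles
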