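"""Network substrates for epidemic simulations.

Generators for the two synthetic ensembles used throughout the package —
random regular networks (RRN) and configuration-model scale-free networks
(SFN) with either a structural (k_max ~ N^{1/2}) or a natural
(k_max ~ N^{1/(gamma-1)}) degree cutoff — plus an edge-list reader/writer
for empirical networks and the degree statistics that all closed-form
threshold predictions consume.

Graphs are undirected and simple.  Internally a :class:`Network` stores a
canonical edge array and a CSR adjacency (``indptr``/``indices``) so the
simulation kernels can traverse neighborhoods without Python overhead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .exceptions import (
    EdgeListParseError,
    GenerationError,
    InvalidParameterError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "DegreeStats",
    "SFNConfig",
    "generate_rrn",
    "generate_sfn",
    "sample_powerlaw_degrees",
    "read_edge_list",
    "write_edge_list",
    "degree_stats",
    "degree_assortativity",
]


@dataclass(frozen=True)
class Network:
    """An undirected simple graph on nodes ``0..n_nodes-1``.

    Attributes
    ----------
    n_nodes:
        Number of nodes N.
    edge_array:
        ``(m, 2)`` integer array of unordered edges, canonicalised so that
        ``edge_array[:, 0] < edge_array[:, 1]`` and rows are sorted.
    indptr, indices:
        CSR adjacency: neighbors of node ``i`` are
        ``indices[indptr[i]:indptr[i + 1]]``.
    """

    n_nodes: int
    edge_array: np.ndarray
    indptr: np.ndarray = field(repr=False)
    indices: np.ndarray = field(repr=False)

    @classmethod
    def from_edges(cls, n_nodes: int, edges) -> "Network":
        """Build a network from an iterable of node pairs.

        Self-loops and duplicate edges are rejected here (generators and the
        edge-list reader deduplicate *before* calling this constructor, with
        logging, so silent data loss cannot occur).
        """
        if n_nodes <= 0:
            raise InvalidParameterError("n_nodes must be positive")
        arr = np.asarray(list(edges) if not isinstance(edges, np.ndarray) else edges,
                         dtype=np.int64)
        if arr.size == 0:
            arr = arr.reshape(0, 2)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise InvalidParameterError("edges must be pairs of node IDs")
        if arr.size and (arr.min() < 0 or arr.max() >= n_nodes):
            raise InvalidParameterError("edge endpoint outside 0..N-1")
        if np.any(arr[:, 0] == arr[:, 1]):
            raise InvalidParameterError("self-loop in edge set")
        canon = np.sort(arr, axis=1)
        canon = canon[np.lexsort((canon[:, 1], canon[:, 0]))]
        if canon.shape[0] > 1 and np.any(np.all(np.diff(canon, axis=0) == 0, axis=1)):
            raise InvalidParameterError("duplicate edge in edge set")
        indptr, indices = _build_csr(n_nodes, canon)
        return cls(n_nodes=n_nodes, edge_array=canon, indptr=indptr, indices=indices)

    @classmethod
    def from_networkx(cls, graph: nx.Graph) -> "Network":
        mapping = {u: i for i, u in enumerate(graph.nodes())}
        edges = [(mapping[u], mapping[v]) for u, v in graph.edges() if u != v]
        return cls.from_edges(graph.number_of_nodes(), edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edge_array))
        return g

    @property
    def n_edges(self) -> int:
        return int(self.edge_array.shape[0])

    @property
    def degrees(self) -> np.ndarray:
        """Degree of every node, as an int64 array."""
        return np.diff(self.indptr)

    def neighbors(self, node: int) -> np.ndarray:
        return self.indices[self.indptr[node]:self.indptr[node + 1]]


def _build_csr(n_nodes: int, edges: np.ndarray):
    deg = np.zeros(n_nodes, dtype=np.int64)
    if edges.size:
        np.add.at(deg, edges[:, 0], 1)
        np.add.at(deg, edges[:, 1], 1)
    indptr = np.zeros(n_nodes + 1, dtype=np.int64)
    np.cumsum(deg, out=indptr[1:])
    indices = np.empty(indptr[-1], dtype=np.int64)
    cursor = indptr[:-1].copy()
    for a, b in edges:
        indices[cursor[a]] = b
        cursor[a] += 1
        indices[cursor[b]] = a
        cursor[b] += 1
    # sort each neighborhood for reproducible traversal order
    for i in range(n_nodes):
        indices[indptr[i]:indptr[i + 1]].sort()
    return indptr, indices


@dataclass(frozen=True)
class DegreeStats:
    """Moments of a realized degree sequence.

    ``mean_k`` and ``mean_k2`` are the first and second moments <k> and <k^2>
    that parameterise every mean-field threshold; ``assortativity_r`` is the
    Pearson correlation of degrees at edge endpoints (NaN on regular graphs,
    whose endpoint degrees have zero variance).
    """

    n_nodes: int
    mean_k: float
    mean_k2: float
    k_max: int
    assortativity_r: float


@dataclass(frozen=True)
class SFNConfig:
    """Configuration-model scale-free ensemble: P(k) ~ k^{-gamma} on
    [k_min, cap], where the cap is floor(N^{1/2}) in ``structural`` mode and
    floor(N^{1/(gamma-1)}) in ``natural`` mode.

    ``k_min`` defaults to 3 so that the giant component dominates for the
    degree exponents of interest (gamma <= 3.5) and the mean outbreak size is
    a smooth function of the transmission rate.
    """

    n_nodes: int
    gamma: float
    k_min: int = 3
    cutoff_mode: str = "structural"

    def __post_init__(self):
        if self.gamma <= 2:
            raise InvalidParameterError("degree exponent gamma must exceed 2")
        if self.k_min < 1:
            raise InvalidParameterError("k_min must be >= 1")
        if self.cutoff_mode not in ("structural", "natural"):
            raise InvalidParameterError(
                f"cutoff_mode must be 'structural' or 'natural', got {self.cutoff_mode!r}")
        if self.k_min >= self.degree_cap:
            raise InvalidParameterError(
                f"k_min={self.k_min} >= degree cap {self.degree_cap} for N={self.n_nodes}")

    @property
    def degree_cap(self) -> int:
        if self.cutoff_mode == "structural":
            return int(np.floor(self.n_nodes ** 0.5))
        return int(np.floor(self.n_nodes ** (1.0 / (self.gamma - 1.0))))


def generate_rrn(n_nodes: int, degree: int, rng_seed: int) -> Network:
    """Random regular network: every node has exactly ``degree`` neighbors.

    Stub-matching with rejection of self-loops and multi-edges (networkx's
    pairing algorithm). Requires ``n_nodes * degree`` even and
    ``degree < n_nodes``.
    """
    if degree >= n_nodes:
        raise InvalidParameterError(f"degree {degree} must be < n_nodes {n_nodes}")
    if (n_nodes * degree) % 2 != 0:
        raise InvalidParameterError(
            f"n_nodes * degree = {n_nodes * degree} is odd: no regular graph exists")
    try:
        g = nx.random_regular_graph(degree, n_nodes, seed=int(rng_seed))
    except nx.NetworkXError as exc:  # pragma: no cover - pairing failure is rare
        raise GenerationError(f"regular-graph pairing failed: {exc}") from exc
    return Network.from_networkx(g)


def sample_powerlaw_degrees(config: SFNConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw N degrees from the exactly normalised discrete power law
    P(k) ∝ k^{-gamma} on [k_min, cap], by inverse-CDF sampling.

    If the stub sum is odd, one uniformly chosen entry is resampled until the
    sum is even.
    """
    ks = np.arange(config.k_min, config.degree_cap + 1, dtype=np.int64)
    weights = ks.astype(float) ** (-config.gamma)
    cdf = np.cumsum(weights)
    cdf /= cdf[-1]
    degrees = ks[np.searchsorted(cdf, rng.random(config.n_nodes))]
    while degrees.sum() % 2 != 0:
        i = rng.integers(config.n_nodes)
        degrees[i] = ks[np.searchsorted(cdf, rng.random())]
    return degrees


_SFN_RETRY_BUDGET = 100


def generate_sfn(config: SFNConfig, rng_seed: int) -> Network:
    """Configuration-model scale-free network under ``config``.

    The degree sequence is drawn with :func:`sample_powerlaw_degrees`; stubs
    are paired uniformly and the multigraph is then simplified by erasing
    self-loops and collapsing multi-edges.  Erasure perturbs the largest
    degrees only mildly under either cutoff (the expected number of erased
    edges is O(k_max^2 / N)); the erased count is logged.
    """
    rng = np.random.default_rng(rng_seed)
    for _ in range(_SFN_RETRY_BUDGET):
        degrees = sample_powerlaw_degrees(config, rng)
        g = nx.configuration_model(degrees, seed=int(rng.integers(2 ** 31)))
        simple = nx.Graph(g)
        simple.remove_edges_from(nx.selfloop_edges(simple))
        erased = g.number_of_edges() - simple.number_of_edges()
        if erased:
            logger.debug("configuration model: erased %d self-loop/multi-edge stubs "
                         "out of %d edges", erased, g.number_of_edges())
        if simple.number_of_edges() > 0:
            return Network.from_networkx(simple)
    raise GenerationError(
        f"could not realize a non-trivial simple graph for {config} "
        f"after {_SFN_RETRY_BUDGET} attempts")


def read_edge_list(path) -> Network:
    """Read an undirected simple graph from a whitespace-separated edge list.

    Lines starting with ``#`` (and blank lines) are ignored.  Node labels may
    be arbitrary integers; they are relabeled to ``0..N-1`` in order of first
    appearance.  Self-loops and duplicate edges are dropped with a logged
    count.
    """
    path = Path(path)
    first_seen: dict[int, int] = {}
    raw_edges: list[tuple[int, int]] = []
    n_self_loops = 0
    with open(path) as fh:
        for line_number, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise EdgeListParseError(path, line_number,
                                         f"expected two fields, got {len(parts)}")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError:
                raise EdgeListParseError(path, line_number,
                                         f"non-integer node label in {line!r}") from None
            for lab in (u, v):
                if lab not in first_seen:
                    first_seen[lab] = len(first_seen)
            if u == v:
                n_self_loops += 1
                continue
            raw_edges.append((u, v) if u < v else (v, u))
    if not first_seen:
        raise EdgeListParseError(path, 0, "no edges found (empty graph)")
    unique_edges = list(dict.fromkeys(raw_edges))
    n_dupes = len(raw_edges) - len(unique_edges)
    if n_self_loops or n_dupes:
        logger.warning("%s: dropped %d self-loops and %d duplicate edges",
                       path, n_self_loops, n_dupes)
    # nodes that only ever appeared in self-loops count as nodes only if
    # referenced by a kept edge
    kept = {lab for e in unique_edges for lab in e}
    if kept == set(range(len(kept))):
        # labels already canonical 0..N-1: keep them, so write -> read
        # round-trips to the identical edge set
        return Network.from_edges(len(kept), unique_edges)
    order = sorted(kept, key=first_seen.__getitem__)
    remap = {lab: i for i, lab in enumerate(order)}
    return Network.from_edges(
        len(kept), [(remap[a], remap[b]) for a, b in unique_edges])


def write_edge_list(network: Network, path) -> None:
    """Write the canonical edge array, one ``u v`` pair per line."""
    with open(path, "w") as fh:
        fh.write(f"# undirected simple graph, N={network.n_nodes}, "
                 f"M={network.n_edges}\n")
        for a, b in network.edge_array:
            fh.write(f"{a} {b}\n")


def degree_stats(network: Network) -> DegreeStats:
    """Exact moments of the realized degree sequence plus assortativity."""
    deg = network.degrees
    if deg.size == 0:
        raise InvalidParameterError("empty network")
    return DegreeStats(
        n_nodes=network.n_nodes,
        mean_k=float(deg.mean()),
        mean_k2=float((deg.astype(float) ** 2).mean()),
        k_max=int(deg.max()),
        assortativity_r=degree_assortativity(network),
    )


def degree_assortativity(network: Network) -> float:
    """Pearson correlation of endpoint degrees over the directed-edge
    expansion (each undirected edge counted in both orientations).

    Returns NaN when the endpoint-degree variance vanishes (regular graphs).
    """
    if network.n_edges == 0:
        return float("nan")
    deg = network.degrees.astype(float)
    src = np.concatenate([network.edge_array[:, 0], network.edge_array[:, 1]])
    dst = np.concatenate([network.edge_array[:, 1], network.edge_array[:, 0]])
    x, y = deg[src], deg[dst]
    vx = x.var()
    if vx == 0.0:
        return float("nan")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov / vx)  # var(x) == var(y) by symmetry of the expansion
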