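"""Closed-form epidemic-threshold predictions.

All formulas are evaluated on the *realized* degree sequence of a given
network instance, not the nominal ensemble law, so that finite-size
comparisons against simulated thresholds are like-for-like.

Predictions implemented (lambda = beta / mu throughout):

==================  ===============================================
heterogeneous MF    SIR: <k> / (<k^2> - <k>);  SIS: <k> / <k^2>
quenched MF         1 / Lambda_N, Lambda_N the leading adjacency
                    eigenvalue (SIR and SIS share the expression)
bond percolation    <k> / (<k^2> - 2<k>), the SIR threshold when
                    infectious periods vary (mu < 1 limit)
edge-based comp.    <k> / (<k^2> + (mu - 2)<k>), interpolating the
                    percolation (mu -> 0) and HMF SIR (mu -> 1) values
==================  ===============================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse
import scipy.sparse.linalg

from .exceptions import DegenerateGraphError, NoFiniteThresholdError, NumericalError
from .netgen import DegreeStats, Network, degree_stats

__all__ = [
    "TheoreticalThresholds",
    "hmf_sir_threshold",
    "hmf_sis_threshold",
    "qmf_threshold",
    "percolation_sir_threshold",
    "ebc_threshold",
    "leading_eigenvalue",
    "compute_thresholds",
]

_EIG_TOL = 1e-8
_EIG_MAXITER = 10_000


@dataclass(frozen=True)
class TheoreticalThresholds:
    """All closed-form predictions for one network (NaN where undefined)."""

    hmf_sir: float
    hmf_sis: float
    qmf: float
    percolation: float
    ebc: float
    lambda_max: float
    mu: float


def hmf_sir_threshold(stats: DegreeStats) -> float:
    """SIR threshold <k> / (<k^2> - <k>) from degree-based mean-field theory.

    On a random regular network of degree k this is exactly 1 / (k - 1).
    """
    denom = stats.mean_k2 - stats.mean_k
    if denom <= 0:
        raise DegenerateGraphError(
            f"<k^2> - <k> = {denom:.4g} <= 0: HMF SIR threshold undefined")
    return stats.mean_k / denom


def hmf_sis_threshold(stats: DegreeStats) -> float:
    """SIS threshold <k> / <k^2> from degree-based mean-field theory."""
    if stats.mean_k2 <= 0:
        raise DegenerateGraphError("graph has no edges: <k^2> = 0")
    return stats.mean_k / stats.mean_k2


def percolation_sir_threshold(stats: DegreeStats) -> float:
    """SIR threshold <k> / (<k^2> - 2<k>) from the bond-percolation mapping
    with heterogeneous infectious periods."""
    denom = stats.mean_k2 - 2.0 * stats.mean_k
    if denom <= 0:
        raise NoFiniteThresholdError(
            f"<k^2> - 2<k> = {denom:.4g} <= 0: no finite percolation threshold")
    return stats.mean_k / denom


def ebc_threshold(stats: DegreeStats, mu: float) -> float:
    """Edge-based compartmental SIR threshold <k> / (<k^2> + (mu - 2)<k>).

    Continuous and monotone in mu on [0, 1]: at mu = 1 it coincides with the
    HMF SIR value, at mu = 0 with the percolation value.
    """
    denom = stats.mean_k2 + (mu - 2.0) * stats.mean_k
    if denom <= 0:
        raise NoFiniteThresholdError(
            f"<k^2> + (mu - 2)<k> = {denom:.4g} <= 0 at mu = {mu}")
    return stats.mean_k / denom


def leading_eigenvalue(network: Network) -> float:
    """Leading eigenvalue Lambda_N of the adjacency matrix, via sparse
    Lanczos iteration (the matrix is never densified)."""
    n = network.n_nodes
    if network.n_edges == 0:
        raise DegenerateGraphError("graph has no edges: Lambda_N = 0")
    data = np.ones(network.indices.size)
    adj = scipy.sparse.csr_matrix(
        (data, network.indices, network.indptr), shape=(n, n))
    if n <= 3:
        return float(np.linalg.eigvalsh(adj.toarray()).max())
    try:
        vals = scipy.sparse.linalg.eigsh(
            adj, k=1, which="LA", tol=_EIG_TOL, maxiter=_EIG_MAXITER,
            return_eigenvectors=False,
            v0=np.ones(n) / np.sqrt(n))
    except scipy.sparse.linalg.ArpackNoConvergence as exc:
        raise NumericalError(
            f"Lanczos iteration did not converge within {_EIG_MAXITER} "
            f"iterations at tol {_EIG_TOL}") from exc
    return float(vals[0])


def qmf_threshold(network: Network) -> float:
    """Quenched mean-field threshold 1 / Lambda_N."""
    lam = leading_eigenvalue(network)
    if lam <= 0:
        raise DegenerateGraphError(f"Lambda_N = {lam:.4g} <= 0")
    return 1.0 / lam


def compute_thresholds(network: Network, mu: float = 1.0,
                       stats: DegreeStats | None = None) -> TheoreticalThresholds:
    """Evaluate every prediction on one network; thresholds whose formula is
    degenerate for this degree sequence come back as NaN."""
    if stats is None:
        stats = degree_stats(network)

    def _safe(fn, *args):
        try:
            return fn(*args)
        except DegenerateGraphError:
            return float("nan")

    lam_max = leading_eigenvalue(network)
    return TheoreticalThresholds(
        hmf_sir=_safe(hmf_sir_threshold, stats),
        hmf_sis=_safe(hmf_sis_threshold, stats),
        qmf=1.0 / lam_max,
        percolation=_safe(percolation_sir_threshold, stats),
        ebc=_safe(ebc_threshold, stats, mu),
        lambda_max=lam_max,
        mu=mu,
    )
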