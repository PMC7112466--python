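"""Numba-compiled inner loops for the stochastic epidemic dynamics.

Both kernels implement the discrete-time (Delta t = 1), synchronous-update
dynamics: in each step every susceptible node with ``n_i`` currently infected
neighbors becomes infected with probability ``1 - (1 - beta)**n_i``
(realised as one independent Bernoulli(beta) trial per infected neighbor),
and every node that was infected at the *start* of the step recovers with
probability ``mu`` after transmitting.  A node infected in step ``t``
therefore first transmits in step ``t + 1`` and can recover at the end of
step ``t + 1`` at the earliest; with ``mu = 1`` the SIR dynamics is exactly
bond percolation with occupation probability ``beta``.

Each realization is seeded independently (``np.random.seed`` per run), so
results depend only on the seed array, not on execution order or batching.
"""

import numpy as np
from numba import njit

__all__ = ["sir_final_sizes", "sis_runs"]


@njit(cache=True)
def sir_final_sizes(indptr, indices, beta, mu, seeds, seed_nodes,
                    out_sizes, out_durations):
    """Run ``len(seeds)`` independent SIR realizations.

    Writes the final recovered fraction into ``out_sizes`` and the number of
    completed time steps into ``out_durations``.
    """
    n = indptr.size - 1
    state = np.zeros(n, np.int8)          # 0 S, 1 I, 2 R
    active = np.empty(n, np.int64)        # nodes infected at start of step
    fresh = np.empty(n, np.int64)         # nodes infected during this step
    touched = np.empty(n, np.int64)       # all ever-infected, for cheap reset
    for r in range(seeds.size):
        np.random.seed(seeds[r])
        s0 = seed_nodes[r]
        state[s0] = 1
        active[0] = s0
        n_active = 1
        touched[0] = s0
        n_touched = 1
        t = 0
        while n_active > 0:
            n_fresh = 0
            for ii in range(n_active):
                i = active[ii]
                for jj in range(indptr[i], indptr[i + 1]):
                    j = indices[jj]
                    if state[j] == 0 and np.random.random() < beta:
                        state[j] = 1
                        fresh[n_fresh] = j
                        n_fresh += 1
                        touched[n_touched] = j
                        n_touched += 1
            n_keep = 0
            for ii in range(n_active):
                i = active[ii]
                if np.random.random() < mu:
                    state[i] = 2
                else:
                    active[n_keep] = i
                    n_keep += 1
            for ii in range(n_fresh):
                active[n_keep] = fresh[ii]
                n_keep += 1
            n_active = n_keep
            t += 1
        out_sizes[r] = n_touched / n
        out_durations[r] = t
        for ii in range(n_touched):
            state[touched[ii]] = 0


@njit(cache=True)
def sis_runs(indptr, indices, beta, mu, t_max, t_window, seeds, seed_nodes,
             out_density, out_survived, out_durations):
    """Run ``len(seeds)`` independent SIS realizations.

    A run that survives to ``t_max`` reports the infected density averaged
    over its final ``t_window`` steps and ``survived = 1``; a run absorbed
    earlier reports density 0 and ``survived = 0``.
    """
    n = indptr.size - 1
    state = np.zeros(n, np.int8)          # 0 S, 1 I
    active = np.empty(n, np.int64)
    fresh = np.empty(n, np.int64)
    for r in range(seeds.size):
        np.random.seed(seeds[r])
        for i in range(n):
            state[i] = 0
        s0 = seed_nodes[r]
        state[s0] = 1
        active[0] = s0
        n_active = 1
        acc = 0.0
        t = 0
        while t < t_max and n_active > 0:
            n_fresh = 0
            for ii in range(n_active):
                i = active[ii]
                for jj in range(indptr[i], indptr[i + 1]):
                    j = indices[jj]
                    if state[j] == 0 and np.random.random() < beta:
                        state[j] = 1
                        fresh[n_fresh] = j
                        n_fresh += 1
            n_keep = 0
            for ii in range(n_active):
                i = active[ii]
                if np.random.random() < mu:
                    state[i] = 0
                else:
                    active[n_keep] = i
                    n_keep += 1
            for ii in range(n_fresh):
                active[n_keep] = fresh[ii]
                n_keep += 1
            n_active = n_keep
            t += 1
            if t > t_max - t_window:
                acc += n_active / n
        if n_active > 0 and t == t_max:
            out_density[r] = acc / t_window
            out_survived[r] = 1
        else:
            out_density[r] = 0.0
            out_survived[r] = 0
        out_durations[r] = t
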