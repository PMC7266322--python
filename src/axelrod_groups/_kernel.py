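"""Compiled inner loop for running the dynamics to absorption.

The event loop is strictly sequential (each copy changes the propensities
of later events), so it is written as a single numba kernel over the
flat CSR neighbor arrays.  The kernel seeds numba's internal Mersenne
Twister, making a run fully reproducible from its integer seed.

Mode flags: mode 0 = standard, 1 = threshold; rule 0 = within_threshold,
1 = literal_two_stage (threshold mode only).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _edges_inactive(traits, edge_u, edge_v, a, mode):  # pragma: no cover - jitted
    """True iff no lattice edge can ever produce a state change."""
    F = traits.shape[1]
    for e in range(edge_u.shape[0]):
        i = edge_u[e]
        j = edge_v[e]
        if mode == 0:
            shared = 0
            for k in range(F):
                if traits[i, k] == traits[j, k]:
                    shared += 1
            if 0 < shared < F:
                return False
        else:
            for k in range(F):
                d = traits[i, k] - traits[j, k]
                if d < 0:
                    d = -d
                if 0 < d <= a:
                    return False
    return True


@njit(cache=True)
def run_kernel(
    traits, indptr, indices, edge_u, edge_v, a, mode, rule, max_steps, check_every, seed
):  # pragma: no cover - jitted
    """Run elementary events in place until absorbing or max_steps.

    Returns (steps, absorbed).  traits is mutated in place.
    """
    np.random.seed(seed)
    N, F = traits.shape
    eligible = np.empty(F, dtype=np.int64)
    steps = 0
    if _edges_inactive(traits, edge_u, edge_v, a, mode):
        return steps, True
    while steps < max_steps:
        block_end = min(steps + check_every, max_steps)
        while steps < block_end:
            i = np.random.randint(0, N)
            deg = indptr[i + 1] - indptr[i]
            j = indices[indptr[i] + np.random.randint(0, deg)]
            steps += 1
            n_prob = 0  # features counting toward the interaction probability
            n_elig = 0  # candidate features for copying
            for k in range(F):
                d = traits[i, k] - traits[j, k]
                if d < 0:
                    d = -d
                if mode == 0:
                    if d == 0:
                        n_prob += 1
                    else:
                        eligible[n_elig] = k
                        n_elig += 1
                else:
                    if d <= a:
                        n_prob += 1
                    if d != 0 and (rule == 1 or d <= a):
                        eligible[n_elig] = k
                        n_elig += 1
            if n_prob == 0:
                continue
            if n_prob < F and np.random.random() * F >= n_prob:
                continue
            if n_elig == 0:
                continue
            k = eligible[np.random.randint(0, n_elig)]
            if rule == 1 and mode == 1:
                d = traits[i, k] - traits[j, k]
                if d < 0:
                    d = -d
                if d > a:
                    continue
            traits[i, k] = traits[j, k]
        if _edges_inactive(traits, edge_u, edge_v, a, mode):
            return steps, True
    return steps, _edges_inactive(traits, edge_u, edge_v, a, mode)
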