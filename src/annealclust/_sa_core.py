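"""Numba kernel for the simulated-annealing sampler.

Each read is an independent Metropolis single-bit-flip anneal.  Local fields
``f_i = sum_j J_ij x_j`` are maintained incrementally so a flip proposal costs
O(1) and an accepted flip O(n).  Reads are seeded individually
(``seed + read``) so the result is independent of read scheduling.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def sa_anneal(j_sym, h, betas, num_reads, seed):  # pragma: no cover - jitted
    n = h.shape[0]
    sweeps = betas.shape[0]
    states = np.empty((num_reads, n), dtype=np.int8)
    for r in range(num_reads):
        np.random.seed((seed + r) % 2147483647)
        x = np.empty(n, dtype=np.int8)
        for i in range(n):
            x[i] = 1 if np.random.random() < 0.5 else 0
        fields = np.zeros(n)
        for i in range(n):
            if x[i] == 1:
                for jj in range(n):
                    fields[jj] += j_sym[i, jj]
        for s in range(sweeps):
            beta = betas[s]
            for i in range(n):
                dx = 1 - 2 * x[i]
                de = dx * (h[i] + fields[i])
                if de <= 0.0 or np.random.random() < np.exp(-beta * de):
                    x[i] += dx
                    for jj in range(n):
                        fields[jj] += dx * j_sym[i, jj]
        states[r] = x
    return states
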