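"""Numba force kernel for the pairwise terms of the chromatin potential.

The per-pair loop runs in lexicographic (i, j) order whether it is given
the full upper triangle or a neighbor list, and terms beyond their cutoffs
contribute exact zeros, so dense and neighbor-list evaluations of the same
configuration are bit-identical whenever the list covers the truncation
radius.
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True)
def pair_forces(x, W, pairs_i, pairs_j, r_c, sigma, r_cut,
                ev_epsilon, ev_range):
    """Non-bonded forces: alpha-weighted contact terms (truncated at
    ``r_cut``; pass inf for no truncation) plus soft-core excluded volume."""
    n = x.shape[0]
    F = np.zeros((n, 3))
    for p in range(pairs_i.shape[0]):
        i = pairs_i[p]
        j = pairs_j[p]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        dudr = 0.0
        w = W[i, j]
        if w != 0.0 and r < r_cut:
            if r <= r_c:
                c = np.cosh(sigma * (r_c - r))
                dudr += w * (-0.5 * sigma / (c * c))
            else:
                dudr += w * (-2.0 * r_c**4 / r**5)
        if r < ev_range:
            s = r / ev_range
            dudr += -4.0 * ev_epsilon * r / ev_range**2 * (1.0 - s * s)
        if dudr != 0.0:
            rs = r if r > 1e-12 else 1e-12
            g = -dudr / rs
            F[i, 0] += g * dx
            F[i, 1] += g * dy
            F[i, 2] += g * dz
            F[j, 0] -= g * dx
            F[j, 1] -= g * dy
            F[j, 2] -= g * dz
    return F
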