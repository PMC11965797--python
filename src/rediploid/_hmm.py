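"""Numba kernels for the along-genome assignment-switching chain.

The hidden chain runs over subgenome-assignment vectors (2^N states for N
genomes) along the pillar order; these recursions are sequential in the
pillar index and are the runtime hot spot of every likelihood evaluation,
hence the JIT.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def forward_loglik(emission: np.ndarray, trans: np.ndarray) -> float:
    """Log-likelihood of the emission matrix under the assignment HMM.

    emission: (n_pillars, K) per-pillar likelihood of each assignment vector;
    trans: (K, K) assignment-flip transition matrix; initial distribution
    uniform.  Scaled forward recursion; returns -inf for an impossible
    dataset instead of raising.
    """
    n, k = emission.shape
    f = np.empty(k)
    for j in range(k):
        f[j] = emission[0, j] / k
    total = 0.0
    s = f.sum()
    if s <= 0.0:
        return -np.inf
    total += np.log(s)
    f /= s
    for i in range(1, n):
        g = np.zeros(k)
        for a in range(k):
            fa = f[a]
            if fa > 0.0:
                for b in range(k):
                    g[b] += fa * trans[a, b]
        for b in range(k):
            g[b] *= emission[i, b]
        s = g.sum()
        if s <= 0.0:
            return -np.inf
        total += np.log(s)
        f = g / s
    return total


@njit(cache=True)
def forward_backward(emission: np.ndarray, trans: np.ndarray) -> np.ndarray:
    """Posterior probability of each assignment vector at each pillar.

    Returns (n_pillars, K); rows sum to 1.  Scaled forward-backward with a
    uniform initial distribution and symmetric transition matrix.
    """
    n, k = emission.shape
    fwd = np.empty((n, k))
    scale = np.empty(n)
    f = emission[0] / k
    s = f.sum()
    if s <= 0.0:
        raise ValueError("zero-probability dataset")
    fwd[0] = f / s
    scale[0] = s
    for i in range(1, n):
        g = np.zeros(k)
        for a in range(k):
            fa = fwd[i - 1, a]
            if fa > 0.0:
                for b in range(k):
                    g[b] += fa * trans[a, b]
        for b in range(k):
            g[b] *= emission[i, b]
        s = g.sum()
        if s <= 0.0:
            raise ValueError("zero-probability dataset")
        fwd[i] = g / s
        scale[i] = s
    post = np.empty((n, k))
    b = np.ones(k)
    post[n - 1] = fwd[n - 1]
    for i in range(n - 2, -1, -1):
        tmp = np.empty(k)
        for a in range(k):
            tmp[a] = emission[i + 1, a] * b[a]
        bn = np.zeros(k)
        for a in range(k):
            for c in range(k):
                bn[a] += trans[a, c] * tmp[c]
        s = bn.sum()
        bn /= s
        b = bn
        row = fwd[i] * b
        post[i] = row / row.sum()
    return post
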