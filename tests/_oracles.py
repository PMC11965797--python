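"""Brute-force reference implementations used only as test oracles.

These deliberately share no code with the package internals: transition
matrices come from a truncated-series matrix exponential, pillar
likelihoods from exhaustive enumeration over all hidden node states, and
dataset likelihoods/posteriors from enumeration over all assignment-vector
sequences.
"""

import itertools

import numpy as np


def series_expm(q: np.ndarray, t: float, terms: int = 40) -> np.ndarray:
    """Truncated Taylor series for exp(Qt), with scaling-and-squaring."""
    norm = np.abs(q * t).sum(axis=1).max()
    n_sq = max(0, int(np.ceil(np.log2(max(norm, 1e-300)))) + 1)
    m = q * t / 2**n_sq
    out = np.eye(q.shape[0])
    acc = np.eye(q.shape[0])
    for k in range(1, terms):
        acc = acc @ m / k
        out = out + acc
    for _ in range(n_sq):
        out = out @ out
    return out


def leaf_partial(code: int, bit: int) -> np.ndarray:
    """Compatibility of hidden states (U,S1,S2,F) with an observation code."""
    v = np.zeros(4)
    if code == 0:  # BOTH
        v[0] = v[3] = 1.0
    elif code == 1:  # TRACK_A_ONLY -> S1 unless the assignment bit is flipped
        v[2 if bit else 1] = 1.0
    else:  # TRACK_B_ONLY
        v[1 if bit else 2] = 1.0
    return v


def brute_pillar_likelihood(tree, q, codes, assignment_bits) -> float:
    """Sum over every joint hidden-state configuration of all nodes.

    The WGD state is U; the root node's state is reached through the root
    branch.  ``assignment_bits`` holds one bit per genome.
    """
    n_nodes = tree.n_nodes
    pmats = [series_expm(q, t) for t in tree.lengths]
    total = 0.0
    for states in itertools.product(range(4), repeat=n_nodes):
        prob = pmats[tree.root][0, states[tree.root]]
        for node in range(n_nodes):
            for child in tree.children[node]:
                prob *= pmats[child][states[node], states[child]]
        for leaf in range(tree.n_leaves):
            prob *= leaf_partial(codes[leaf], assignment_bits[leaf])[states[leaf]]
        total += prob
    return total


def brute_dataset_likelihood(tree, q, codes, theta) -> float:
    """Sum over all assignment-vector sequences of the joint probability."""
    n_pillars, n_genomes = codes.shape
    k = 2**n_genomes
    vectors = list(itertools.product((0, 1), repeat=n_genomes))
    total = 0.0
    for seq in itertools.product(range(k), repeat=n_pillars):
        prob = 1.0 / k
        for i in range(1, n_pillars):
            prev, cur = vectors[seq[i - 1]], vectors[seq[i]]
            for g in range(n_genomes):
                prob *= theta if prev[g] != cur[g] else 1.0 - theta
        for i in range(n_pillars):
            prob *= brute_pillar_likelihood(tree, q, codes[i], vectors[seq[i]])
        total += prob
    return total


def brute_assignment_posterior(tree, q, codes, theta) -> np.ndarray:
    """Posterior over assignment vectors per pillar by full enumeration."""
    n_pillars, n_genomes = codes.shape
    k = 2**n_genomes
    vectors = list(itertools.product((0, 1), repeat=n_genomes))
    post = np.zeros((n_pillars, k))
    for seq in itertools.product(range(k), repeat=n_pillars):
        prob = 1.0 / k
        for i in range(1, n_pillars):
            prev, cur = vectors[seq[i - 1]], vectors[seq[i]]
            for g in range(n_genomes):
                prob *= theta if prev[g] != cur[g] else 1.0 - theta
        for i in range(n_pillars):
            prob *= brute_pillar_likelihood(tree, q, codes[i], vectors[seq[i]])
        for i in range(n_pillars):
            post[i, seq[i]] += prob
    return post / post.sum(axis=1, keepdims=True)


def brute_leaf_state_posterior(tree, q, codes, assignment_bits) -> np.ndarray:
    """Joint-enumeration posterior over each leaf's hidden state."""
    n_nodes = tree.n_nodes
    pmats = [series_expm(q, t) for t in tree.lengths]
    post = np.zeros((tree.n_leaves, 4))
    for states in itertools.product(range(4), repeat=n_nodes):
        prob = pmats[tree.root][0, states[tree.root]]
        for node in range(n_nodes):
            for child in tree.children[node]:
                prob *= pmats[child][states[node], states[child]]
        for leaf in range(tree.n_leaves):
            prob *= leaf_partial(codes[leaf], assignment_bits[leaf])[states[leaf]]
        for leaf in range(tree.n_leaves):
            post[leaf, states[leaf]] += prob
    return post / post.sum(axis=1, keepdims=True)
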