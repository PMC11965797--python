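"""Fixation posteriors and the sliding-window genome scan.

For each pillar and each leaf genome i, ``p_fix^i`` is the posterior
probability that the ohnolog pair is in the fixed state F at that leaf
(because F is absorbing, this equals the probability that fixation occurred
along any branch on the path to that leaf).  The probability of no fixation
at the pillar is the product p_nonfix = prod_i (1 - p_fix^i), and
1 - p_nonfix, averaged over a sliding window of a fixed fraction of the
pillars, yields the genome scan with its fixation hot and cold spots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .loss_models import (
    HiddenState,
    LossModelSpec,
    LossParams,
    _assignment_bits,
    _assignment_transition,
    _branch_matrices,
    _collapse_patterns,
    _BASE_PARTIALS,
)
from ._hmm import forward_backward
from .pillar_io import Phylogeny, PillarTable, derive_observation_codes

__all__ = [
    "FixationScan",
    "state_posteriors",
    "p_nonfix",
    "sliding_window_mean",
    "fixation_scan",
]


def _leaf_state_posteriors_by_pattern(
    tree: Phylogeny,
    spec: LossModelSpec,
    params: LossParams,
    patterns: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Inside-outside posteriors per (pattern, assignment vector, leaf, state).

    Returns (posteriors, emissions): posteriors has shape
    (n_patterns, 2^N, n_leaves, 4); emissions (n_patterns, 2^N).
    """
    n_genomes = tree.n_leaves
    bits = _assignment_bits(n_genomes)
    pmats = _branch_matrices(tree, spec, params)
    up: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node < n_genomes:
            part = _BASE_PARTIALS[patterns[:, node][:, None], bits[None, :, node], :]
        else:
            msgs = [up[c] @ pmats[c].T for c in tree.children[node]]
            part = msgs[0] * msgs[1]
        up[node] = part
    emissions = up[tree.root] @ pmats[tree.root][HiddenState.U.value]

    outside: dict[int, np.ndarray] = {}
    root_row = pmats[tree.root][HiddenState.U.value]  # P(U -> s) over the root branch
    shape = up[tree.root].shape
    outside[tree.root] = np.broadcast_to(root_row, shape).copy()
    for node in reversed(tree.postorder()):
        if not tree.children[node]:
            continue
        a, b = tree.children[node]
        msg_a = up[a] @ pmats[a].T
        msg_b = up[b] @ pmats[b].T
        outside[a] = (outside[node] * msg_b) @ pmats[a]
        outside[b] = (outside[node] * msg_a) @ pmats[b]

    n_pat, k = patterns.shape[0], bits.shape[0]
    post = np.empty((n_pat, k, n_genomes, 4))
    for leaf in range(n_genomes):
        joint = outside[leaf] * up[leaf]
        total = joint.sum(axis=-1, keepdims=True)
        post[:, :, leaf, :] = joint / np.where(total > 0, total, 1.0)
    return post, emissions


def state_posteriors(
    tree: Phylogeny,
    spec: LossModelSpec,
    params: LossParams,
    table: PillarTable | np.ndarray,
) -> np.ndarray:
    """Per-pillar, per-leaf posterior over (U, S1, S2, F).

    Marginalizes over assignment vectors with forward-backward weights from
    the along-genome assignment chain; rows sum to 1.  Requires a model
    flavor with fixation (otherwise the F posterior is identically zero by
    construction and the scan is undefined).
    """
    if not spec.flavor.has_fixation:
        raise ValueError(
            f"fixation posterior undefined under {spec.flavor.name}: use WGD_f or WGD_bf"
        )
    if isinstance(table, PillarTable):
        codes = derive_observation_codes(table)
        order = [table.genome_labels.index(lab) for lab in tree.leaf_labels]
        codes = codes[:, order]
    else:
        codes = np.asarray(table, dtype=np.int8)
    patterns, inverse = _collapse_patterns(codes)
    by_pattern, em_pat = _leaf_state_posteriors_by_pattern(tree, spec, params, patterns)
    trans = _assignment_transition(tree.n_leaves, params.switch_prob)
    weights = forward_backward(em_pat[inverse], trans)  # (n_pillars, K)
    return np.einsum("pk,pkls->pls", weights, by_pattern[inverse])


def p_nonfix(p_fix_values: np.ndarray) -> float:
    """Probability of no fixation in any genome: prod_i (1 - p_fix^i)."""
    v = np.asarray(p_fix_values, dtype=float)
    if np.any((v < 0) | (v > 1)):
        raise ValueError("fixation probabilities must lie in [0, 1]")
    return float(np.prod(1.0 - v))


def sliding_window_mean(
    series: np.ndarray, window_frac: float
) -> tuple[np.ndarray, np.ndarray]:
    """Centered sliding-window average over the pillar order.

    Window width = max(1, round(window_frac * N)) pillars, stepped one pillar
    at a time; windows are truncated at the edges (no wrap-around).  Returns
    (scaled positions in [0, 1], window means).
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if n == 0:
        raise ValueError("empty series")
    if not 0 < window_frac <= 1:
        raise ValueError("window_frac must be in (0, 1]")
    width = max(1, round(window_frac * n))
    half = width // 2
    csum = np.concatenate(([0.0], np.cumsum(series)))
    lo = np.clip(np.arange(n) - half, 0, n - 1)
    hi = np.clip(np.arange(n) - half + width - 1, 0, n - 1)
    means = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    positions = np.arange(n) / (n - 1) if n > 1 else np.zeros(1)
    return positions, means


@dataclass
class FixationScan:
    """Per-pillar fixation probabilities and their windowed averages."""

    genome_labels: tuple[str, ...]
    p_fix: np.ndarray  # (n_pillars, n_genomes) posterior of F at each leaf
    p_nonfix: np.ndarray  # (n_pillars,)
    one_minus_p_nonfix: np.ndarray
    positions: np.ndarray  # scaled pillar positions in [0, 1]
    window_means: np.ndarray  # windowed 1 - p_nonfix
    window_frac: float


def fixation_scan(
    tree: Phylogeny,
    spec: LossModelSpec,
    params: LossParams,
    table: PillarTable | np.ndarray,
    window_frac: float = 0.02,
) -> FixationScan:
    """The genome scan: fixation posteriors, p_nonfix and 2% window means."""
    post = state_posteriors(tree, spec, params, table)
    p_fix = post[:, :, HiddenState.F.value]
    nonfix = np.prod(1.0 - p_fix, axis=1)
    positions, means = sliding_window_mean(1.0 - nonfix, window_frac)
    return FixationScan(
        genome_labels=tree.leaf_labels,
        p_fix=p_fix,
        p_nonfix=nonfix,
        one_minus_p_nonfix=1.0 - nonfix,
        positions=positions,
        window_means=means,
        window_frac=window_frac,
    )
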