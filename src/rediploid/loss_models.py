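"""Continuous-time Markov models of ohnolog loss after whole-genome duplication.

Every ohnolog pair starts in state U (both copies, undifferentiated)
immediately after the WGD.  Loss of the subgenome-2 copy moves the pair to
S1 (only the subgenome-1 copy survives), loss of the subgenome-1 copy to S2,
and fixation to F, after which no loss can occur.  Four nested model
flavors:

* ``WGD_n`` — equal loss rates to both subgenomes, no fixation;
* ``WGD_b`` — biased fractionation: loss toward S2 at relative rate
  ``epsilon`` in [0, 1], so subgenome 1 is increasingly favored as epsilon
  decreases;
* ``WGD_f`` — fixation at relative rate ``gamma`` >= 0;
* ``WGD_bf`` — both.

The base loss rate is fixed to 1, so branch lengths are in expected-loss
units.  Which observed track (a/b) corresponds to which subgenome is not
known; a hidden assignment vector (one bit per genome) is tracked along the
pillar order as a Markov chain with a per-pillar, per-genome flip
probability ``switch_prob``, and likelihoods sum over all 2^N vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

from ._hmm import forward_backward, forward_loglik
from .pillar_io import ObservationCode, Phylogeny, PillarTable, derive_observation_codes

__all__ = [
    "HiddenState",
    "ModelFlavor",
    "LossModelSpec",
    "LossParams",
    "AssignmentPosterior",
    "build_rate_matrix",
    "transition_matrix",
    "pillar_conditional_likelihood",
    "dataset_loglik",
    "assignment_confidence",
    "n_assignment_vectors",
]

GAMMA_MAX = 100.0  # optimizer stand-in for an unbounded fixation rate


class HiddenState(Enum):
    U = 0  # both copies, undifferentiated
    S1 = 1  # only the subgenome-1 copy
    S2 = 2  # only the subgenome-2 copy
    F = 3  # fixed pair: both copies, loss-immune


class ModelFlavor(Enum):
    WGD_n = "n"
    WGD_b = "b"
    WGD_f = "f"
    WGD_bf = "bf"

    @property
    def has_bias(self) -> bool:
        return self in (ModelFlavor.WGD_b, ModelFlavor.WGD_bf)

    @property
    def has_fixation(self) -> bool:
        return self in (ModelFlavor.WGD_f, ModelFlavor.WGD_bf)


@dataclass(frozen=True)
class LossModelSpec:
    """Which of the four nested loss models is in force."""

    flavor: ModelFlavor

    def validate_params(self, epsilon: float, gamma: float) -> None:
        if not 0.0 <= epsilon <= 1.0:
            raise ValueError(f"epsilon must be in [0, 1], got {epsilon}")
        if not 0.0 <= gamma <= GAMMA_MAX:
            raise ValueError(f"gamma must be in [0, {GAMMA_MAX}], got {gamma}")
        if not self.flavor.has_bias and epsilon != 1.0:
            raise ValueError(f"epsilon is fixed to 1 under {self.flavor.name}")
        if not self.flavor.has_fixation and gamma != 0.0:
            raise ValueError(f"gamma is fixed to 0 under {self.flavor.name}")


@dataclass
class LossParams:
    """Full parameter vector of a loss model on a given tree.

    ``branch_lengths`` is aligned with ``Phylogeny.lengths`` (one entry per
    node; the root entry is the root-branch length from the WGD to the first
    speciation).  ``switch_prob`` is the per-pillar, per-genome probability
    that the subgenome assignment flips between adjacent pillars.
    """

    epsilon: float
    gamma: float
    branch_lengths: np.ndarray
    switch_prob: float = 0.01

    def __post_init__(self) -> None:
        self.branch_lengths = np.asarray(self.branch_lengths, dtype=float)
        if np.any(self.branch_lengths < 0):
            raise ValueError("branch lengths must be non-negative")
        if not 0.0 <= self.switch_prob <= 0.5:
            raise ValueError("switch_prob must be in [0, 0.5]")

    def on_tree(self, tree: Phylogeny) -> Phylogeny:
        return tree.with_lengths(self.branch_lengths)

    def replace(self, **kw) -> "LossParams":
        return replace(self, **kw)


def build_rate_matrix(
    spec: LossModelSpec, epsilon: float = 1.0, gamma: float = 0.0
) -> np.ndarray:
    """4x4 rate matrix over (U, S1, S2, F).

    From U: to S1 at rate 1 (loss of the subgenome-2 copy), to S2 at rate
    ``epsilon``, to F at rate ``gamma``.  S1, S2 and F are absorbing.
    """
    spec.validate_params(epsilon, gamma)
    q = np.zeros((4, 4))
    q[0, 1] = 1.0
    q[0, 2] = epsilon
    q[0, 3] = gamma
    q[0, 0] = -(1.0 + epsilon + gamma)
    return q


def transition_matrix(q: np.ndarray, t: float) -> np.ndarray:
    """exp(Q t) in closed form for the single-transient-state chain.

    Only U is transient, so P(U->U) = exp(-lam t) with lam = 1+eps+gamma and
    the absorption probabilities split pro rata among the absorbing states;
    rows S1, S2, F are identity rows.
    """
    if t < 0:
        raise ValueError("branch length must be non-negative")
    lam = -q[0, 0]
    p = np.eye(4)
    if lam == 0.0:
        return p
    decay = np.exp(-lam * t)
    p[0, 0] = decay
    p[0, 1:] = q[0, 1:] / lam * (1.0 - decay)
    return p


# ---------------------------------------------------------------------------
# Leaf observation model
#
# BOTH is compatible with hidden states {U, F}; a single-copy observation,
# after applying the genome's assignment bit, pins the hidden state to S1 or
# S2.  base_partials[code, bit, state].

_BASE_PARTIALS = np.zeros((3, 2, 4))
_BASE_PARTIALS[ObservationCode.BOTH, :, HiddenState.U.value] = 1.0
_BASE_PARTIALS[ObservationCode.BOTH, :, HiddenState.F.value] = 1.0
_BASE_PARTIALS[ObservationCode.TRACK_A_ONLY, 0, HiddenState.S1.value] = 1.0
_BASE_PARTIALS[ObservationCode.TRACK_A_ONLY, 1, HiddenState.S2.value] = 1.0
_BASE_PARTIALS[ObservationCode.TRACK_B_ONLY, 0, HiddenState.S2.value] = 1.0
_BASE_PARTIALS[ObservationCode.TRACK_B_ONLY, 1, HiddenState.S1.value] = 1.0


def n_assignment_vectors(n_genomes: int) -> int:
    """Number of possible subgenome-assignment vectors for N genomes (2^N)."""
    return 1 << n_genomes


def _assignment_bits(n_genomes: int) -> np.ndarray:
    """(2^N, N) matrix of assignment bits; vector k has bit g = (k >> g) & 1."""
    k = n_assignment_vectors(n_genomes)
    return (np.arange(k)[:, None] >> np.arange(n_genomes)[None, :]) & 1


def _branch_matrices(tree: Phylogeny, spec: LossModelSpec, params: LossParams):
    q = build_rate_matrix(spec, params.epsilon, params.gamma)
    return [transition_matrix(q, t) for t in params.branch_lengths]


def _pattern_emissions(
    tree: Phylogeny,
    spec: LossModelSpec,
    params: LossParams,
    patterns: np.ndarray,
) -> np.ndarray:
    """Pruning likelihood for each code pattern under each assignment vector.

    patterns: (n_patterns, n_genomes) of ObservationCode ints.  Returns
    (n_patterns, 2^N).  Vectorized Felsenstein pruning over patterns and
    assignment vectors simultaneously; the root hidden state is U with
    probability 1, reached through the root branch.
    """
    n_genomes = tree.n_leaves
    bits = _assignment_bits(n_genomes)  # (K, N)
    pmats = _branch_matrices(tree, spec, params)
    partial: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node < n_genomes:
            part = _BASE_PARTIALS[patterns[:, node][:, None], bits[None, :, node], :]
        else:
            msgs = [partial.pop(c) @ pmats[c].T for c in tree.children[node]]
            part = msgs[0] * msgs[1]
        partial[node] = part
    root_part = partial[tree.root]
    p_root = pmats[tree.root]  # root branch: from the WGD (state U) down
    return root_part @ p_root[HiddenState.U.value]


def pillar_conditional_likelihood(
    tree: Phylogeny,
    spec: LossModelSpec,
    params: LossParams,
    codes: np.ndarray,
    assignment: int,
) -> float:
    """Likelihood of one pillar's codes under a fixed assignment vector.

    ``codes`` is one ObservationCode per genome (ordered as
    ``tree.leaf_labels``); ``assignment`` indexes the vector whose bit g
    says whether genome g's track a maps to subgenome 2.
    """
    codes = np.asarray(codes, dtype=np.int8).reshape(1, -1)
    if codes.shape[1] != tree.n_leaves:
        raise ValueError("one observation code per genome is required")
    em = _pattern_emissions(tree, spec, params, codes)
    return float(em[0, assignment])


def _collapse_patterns(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique code patterns and the per-pillar pattern index."""
    patterns, inverse = np.unique(codes, axis=0, return_inverse=True)
    return patterns.astype(np.int8), inverse


def _assignment_transition(n_genomes: int, theta: float) -> np.ndarray:
    """2^N x 2^N assignment-flip kernel: independent per-genome flips."""
    per_genome = np.array([[1.0 - theta, theta], [theta, 1.0 - theta]])
    trans = np.ones((1, 1))
    for _ in range(n_genomes):
        trans = np.kron(per_genome, trans)
    return trans


def _emission_matrix(tree, spec, params, table_or_codes) -> np.ndarray:
    if isinstance(table_or_codes, PillarTable):
        if set(table_or_codes.genome_labels) != set(tree.leaf_labels):
            raise ValueError("tree leaf labels do not match pillar-table genomes")
        codes = derive_observation_codes(table_or_codes)
        # reorder columns to the tree's (sorted) leaf order
        order = [table_or_codes.genome_labels.index(lab) for lab in tree.leaf_labels]
        codes = codes[:, order]
    else:
        codes = np.asarray(table_or_codes, dtype=np.int8)
    patterns, inverse = _collapse_patterns(codes)
    em_pat = _pattern_emissions(tree, spec, params, patterns)
    return em_pat[inverse]


def dataset_loglik(
    tree: Phylogeny,
    spec: LossModelSpec,
    params: LossParams,
    table: PillarTable | np.ndarray,
) -> float:
    """Log-likelihood of a pillar table under the loss model.

    Forward algorithm over the pillar-ordered hidden chain of assignment
    vectors (uniform initial distribution, independent per-genome flips with
    probability ``switch_prob``), with the pruning likelihood of each pillar
    as emission.  Returns -inf (with a warning) for a zero-probability
    dataset under degenerate parameters.
    """
    emission = _emission_matrix(tree, spec, params, table)
    trans = _assignment_transition(tree.n_leaves, params.switch_prob)
    ll = forward_loglik(emission, trans)
    if not np.isfinite(ll):
        warnings.warn("zero-probability dataset under these parameters")
    return float(ll)


@dataclass
class AssignmentPosterior:
    """Per-pillar posterior over subgenome-assignment vectors.

    ``posterior[i, k]`` is the probability that pillar i carries assignment
    vector k (bit g of k: genome g's track a maps to subgenome 2).  ``c``
    is the per-pillar confidence in the modal vector, the quantity plotted
    above pillar columns in synteny browsers.
    """

    genome_labels: tuple[str, ...]
    posterior: np.ndarray  # (n_pillars, 2^N)
    modal_assignment: np.ndarray  # (n_pillars,) int
    c: np.ndarray  # (n_pillars,)


def assignment_confidence(
    tree: Phylogeny,
    spec: LossModelSpec,
    params: LossParams,
    table: PillarTable | np.ndarray,
) -> AssignmentPosterior:
    """Forward-backward posteriors over assignment vectors, per pillar."""
    emission = _emission_matrix(tree, spec, params, table)
    trans = _assignment_transition(tree.n_leaves, params.switch_prob)
    post = forward_backward(emission, trans)
    modal = np.argmax(post, axis=1)
    return AssignmentPosterior(
        genome_labels=tree.leaf_labels,
        posterior=post,
        modal_assignment=modal,
        c=post[np.arange(post.shape[0]), modal],
    )
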