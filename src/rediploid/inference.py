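"""Maximum-likelihood fitting of the loss models and exhaustive tree search.

The optimizer is bounded L-BFGS-B over log branch lengths, the bias epsilon,
log fixation rate gamma and the assignment switch probability theta, with
seeded random restarts (the theta chain can make the surface mildly
multimodal).  Topology search enumerates all (2n-3)!! rooted bifurcating
topologies and fits each; nested model comparisons use the chi-square
likelihood-ratio test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .loss_models import (
    GAMMA_MAX,
    LossModelSpec,
    LossParams,
    ModelFlavor,
    _assignment_transition,
    _collapse_patterns,
    _pattern_emissions,
)
from ._hmm import forward_loglik
from .pillar_io import ObservationCode, Phylogeny, PillarTable, derive_observation_codes

__all__ = [
    "FitResult",
    "TopologySearchResult",
    "fit_model",
    "fit_model_family",
    "count_rooted_topologies",
    "enumerate_topologies",
    "exhaustive_topology_search",
    "lrt",
    "retention_summary",
    "RetentionSummary",
]

_LEN_LO, _LEN_HI = 1e-6, 50.0
_THETA_LO, _THETA_HI = 1e-6, 0.5
_GAMMA_LO = 1e-8


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    spec: LossModelSpec
    tree: Phylogeny  # with fitted branch lengths
    params: LossParams
    lnl: float
    converged: bool
    n_restarts: int
    diagnostics: dict = field(default_factory=dict)


@dataclass
class TopologySearchResult:
    """All rooted topologies with their fits, best first by lnL."""

    results: list[tuple[Phylogeny, FitResult]]
    best: FitResult

    @property
    def lnls(self) -> np.ndarray:
        return np.array([fit.lnl for _, fit in self.results])


def _codes_for_tree(table: PillarTable, tree: Phylogeny) -> np.ndarray:
    codes = derive_observation_codes(table)
    order = [table.genome_labels.index(lab) for lab in tree.leaf_labels]
    return codes[:, order]


class _Objective:
    """Negative log-likelihood over the free-parameter vector.

    Layout: [ln(t) for free branches] + [epsilon] + [ln(gamma)] + [theta],
    each block present only when free under the model/constraints.
    """

    def __init__(
        self,
        tree: Phylogeny,
        spec: LossModelSpec,
        codes: np.ndarray,
        constraints: dict | None,
    ) -> None:
        constraints = dict(constraints or {})
        self.tree = tree
        self.spec = spec
        self.patterns, self.inverse = _collapse_patterns(codes)
        self.fixed_lengths = {}
        for key, val in list(constraints.items()):
            if isinstance(key, str) and key.startswith("branch:"):
                self.fixed_lengths[int(key.split(":")[1])] = float(val)
                del constraints[key]
        self.free_branches = [
            i for i in range(tree.n_nodes) if i not in self.fixed_lengths
        ]
        self.fixed_epsilon = (
            constraints.pop("epsilon", None)
            if spec.flavor.has_bias
            else 1.0
        )
        self.fixed_gamma = (
            constraints.pop("gamma", None) if spec.flavor.has_fixation else 0.0
        )
        self.fixed_theta = constraints.pop("switch_prob", None)
        if constraints:
            raise ValueError(f"unknown constraints: {sorted(constraints)}")

    @property
    def n_free(self) -> int:
        n = len(self.free_branches)
        n += self.fixed_epsilon is None
        n += self.fixed_gamma is None
        n += self.fixed_theta is None
        return n

    def bounds(self) -> list[tuple[float, float]]:
        b = [(np.log(_LEN_LO), np.log(_LEN_HI))] * len(self.free_branches)
        if self.fixed_epsilon is None:
            b.append((1e-6, 1.0))
        if self.fixed_gamma is None:
            b.append((np.log(_GAMMA_LO), np.log(GAMMA_MAX)))
        if self.fixed_theta is None:
            b.append((_THETA_LO, _THETA_HI))
        return b

    def pack(self, params: LossParams) -> np.ndarray:
        x = [np.log(np.clip(params.branch_lengths[i], _LEN_LO, _LEN_HI))
             for i in self.free_branches]
        if self.fixed_epsilon is None:
            x.append(np.clip(params.epsilon, 1e-6, 1.0))
        if self.fixed_gamma is None:
            x.append(np.log(np.clip(params.gamma, _GAMMA_LO, GAMMA_MAX)))
        if self.fixed_theta is None:
            x.append(np.clip(params.switch_prob, _THETA_LO, _THETA_HI))
        return np.array(x)

    def unpack(self, x: np.ndarray) -> LossParams:
        lengths = np.zeros(self.tree.n_nodes)
        for i, node in enumerate(self.free_branches):
            lengths[node] = np.exp(x[i])
        for node, val in self.fixed_lengths.items():
            lengths[node] = val
        k = len(self.free_branches)
        if self.fixed_epsilon is None:
            epsilon = float(np.clip(x[k], 0.0, 1.0)); k += 1
        else:
            epsilon = float(self.fixed_epsilon)
        if self.fixed_gamma is None:
            gamma = float(np.clip(np.exp(x[k]), 0.0, GAMMA_MAX)); k += 1
        else:
            gamma = float(self.fixed_gamma)
        if self.fixed_theta is None:
            theta = float(x[k]); k += 1
        else:
            theta = float(self.fixed_theta)
        return LossParams(
            epsilon=epsilon, gamma=gamma, branch_lengths=lengths, switch_prob=theta
        )

    def loglik(self, params: LossParams) -> float:
        em_pat = _pattern_emissions(self.tree, self.spec, params, self.patterns)
        emission = em_pat[self.inverse]
        trans = _assignment_transition(self.tree.n_leaves, params.switch_prob)
        return forward_loglik(emission, trans)

    def __call__(self, x: np.ndarray) -> float:
        ll = self.loglik(self.unpack(x))
        return -ll if np.isfinite(ll) else 1e12


def _heuristic_start(
    tree: Phylogeny, spec: LossModelSpec, codes: np.ndarray
) -> LossParams:
    lengths = np.full(tree.n_nodes, 0.1)
    for g in range(tree.n_leaves):
        frac_both = float(np.mean(codes[:, g] == ObservationCode.BOTH))
        lengths[g] = np.clip(-np.log(max(frac_both, 0.02)), 0.02, 5.0)
    return LossParams(
        epsilon=0.8 if spec.flavor.has_bias else 1.0,
        gamma=0.1 if spec.flavor.has_fixation else 0.0,
        branch_lengths=lengths,
        switch_prob=0.02,
    )


def _random_start(
    rng: np.random.Generator, tree: Phylogeny, spec: LossModelSpec, base: LossParams
) -> LossParams:
    lengths = base.branch_lengths * np.exp(rng.normal(0.0, 0.7, tree.n_nodes))
    return LossParams(
        epsilon=float(rng.uniform(0.1, 1.0)) if spec.flavor.has_bias else 1.0,
        gamma=float(np.exp(rng.uniform(np.log(0.01), np.log(2.0))))
        if spec.flavor.has_fixation
        else 0.0,
        branch_lengths=np.clip(lengths, _LEN_LO, _LEN_HI),
        switch_prob=float(np.exp(rng.uniform(np.log(1e-3), np.log(0.2)))),
    )


def fit_model(
    table: PillarTable,
    topology: Phylogeny,
    spec: LossModelSpec,
    constraints: dict | None = None,
    seed: int = 0,
    n_restarts: int = 5,
    start: LossParams | None = None,
    tol: float = 1e-11,
) -> FitResult:
    """Maximize the dataset log-likelihood over all free parameters.

    ``constraints`` fixes parameters: keys ``epsilon``, ``gamma``,
    ``switch_prob`` or ``branch:<node index>`` (use ``branch:<root>`` for a
    zero-length root branch).  Deterministic given ``seed``; multi-start
    L-BFGS-B, best of ``n_restarts`` starts.  ``start`` warm-starts the
    first attempt.
    """
    codes = _codes_for_tree(table, topology)
    obj = _Objective(topology, spec, codes, constraints)
    rng = np.random.default_rng(seed)
    base = _heuristic_start(topology, spec, codes)
    starts = [start if start is not None else base]
    while len(starts) < max(1, n_restarts):
        starts.append(_random_start(rng, topology, spec, base))
    best = None
    n_evals = 0
    runs = []
    for s in starts:
        x0 = obj.pack(s)
        res = minimize(
            obj, x0, method="L-BFGS-B", bounds=obj.bounds(),
            options={"maxiter": 1000, "ftol": tol, "gtol": 1e-8},
        )
        n_evals += res.nfev
        runs.append(res)
        if best is None or res.fun < best.fun:
            best = res
    params = obj.unpack(best.x)
    lnl = float(-best.fun)
    # converged if any start that reached the best optimum terminated cleanly,
    # or if the best point is first-order optimal (projected gradient ~ 0;
    # line searches can exit abnormally on flat boundary optima)
    clean = any(r.success and r.fun <= best.fun + 1e-6 for r in runs)
    if not clean and best.jac is not None:
        proj = np.array(best.jac, dtype=float)
        for i, (lo, hi) in enumerate(obj.bounds()):
            if (best.x[i] - lo < 1e-9 and proj[i] > 0) or (
                hi - best.x[i] < 1e-9 and proj[i] < 0
            ):
                proj[i] = 0.0
        clean = np.max(np.abs(proj)) < 0.05
    return FitResult(
        spec=spec,
        tree=topology.with_lengths(params.branch_lengths),
        params=params,
        lnl=lnl,
        converged=clean and np.isfinite(lnl),
        n_restarts=len(starts),
        diagnostics={"n_evals": n_evals, "message": str(best.message)},
    )


def fit_model_family(
    table: PillarTable,
    topology: Phylogeny,
    seed: int = 0,
    n_restarts: int = 5,
    constraints: dict | None = None,
) -> dict[ModelFlavor, FitResult]:
    """Fit all four nested loss models with warm-started, monotone likelihoods.

    Richer models start from the nested optimum (with the freed parameter
    nudged off its boundary); if the optimizer still lands below the nested
    optimum — a feasible point of the richer model — the nested optimum is
    reported instead, so lnL(WGD_bf) >= lnL(WGD_b), lnL(WGD_f) >= lnL(WGD_n)
    hold exactly.  This is the fitting path behind nested LRT comparisons.
    """

    def embed(fit: FitResult, spec: LossModelSpec) -> FitResult:
        return FitResult(
            spec=spec, tree=fit.tree, params=fit.params, lnl=fit.lnl,
            converged=fit.converged, n_restarts=fit.n_restarts,
            diagnostics=dict(fit.diagnostics, embedded_from=fit.spec.flavor.name),
        )

    def fit_from(spec: LossModelSpec, starts: list[LossParams], nested: list[FitResult]):
        best = None
        for i, s in enumerate(starts):
            f = fit_model(
                table, topology, spec, constraints=constraints,
                seed=seed + i, n_restarts=n_restarts, start=s,
            )
            if best is None or f.lnl > best.lnl:
                best = f
        for n in nested:
            if n.lnl > best.lnl:
                best = embed(n, spec)
        return best

    out: dict[ModelFlavor, FitResult] = {}
    spec_n = LossModelSpec(ModelFlavor.WGD_n)
    fit_n = fit_model(
        table, topology, spec_n, constraints=constraints, seed=seed,
        n_restarts=n_restarts,
    )
    out[ModelFlavor.WGD_n] = fit_n
    start_b = fit_n.params.replace(epsilon=0.95)
    out[ModelFlavor.WGD_b] = fit_from(
        LossModelSpec(ModelFlavor.WGD_b), [start_b], [fit_n]
    )
    start_f = fit_n.params.replace(gamma=0.05)
    out[ModelFlavor.WGD_f] = fit_from(
        LossModelSpec(ModelFlavor.WGD_f), [start_f], [fit_n]
    )
    fit_b, fit_f = out[ModelFlavor.WGD_b], out[ModelFlavor.WGD_f]
    starts_bf = [
        fit_b.params.replace(gamma=max(fit_b.params.gamma, 0.05)),
        fit_f.params.replace(epsilon=min(fit_f.params.epsilon, 0.95)),
    ]
    out[ModelFlavor.WGD_bf] = fit_from(
        LossModelSpec(ModelFlavor.WGD_bf), starts_bf, [fit_b, fit_f]
    )
    return out


# ---------------------------------------------------------------------------
# Topology enumeration


def count_rooted_topologies(n_leaves: int) -> int:
    """(2n-3)!! rooted bifurcating topologies on n labeled leaves."""
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    out = 1
    for k in range(3, 2 * n_leaves - 2, 2):
        out *= k
    return out


def _insert_leaf(shape, leaf):
    """All shapes obtained by attaching ``leaf`` on any edge or above the root."""
    yield (shape, leaf)
    if isinstance(shape, tuple):
        a, b = shape
        for sub in _insert_leaf(a, leaf):
            yield (sub, b)
        for sub in _insert_leaf(b, leaf):
            yield (a, sub)


def _shape_to_phylogeny(shape, labels: tuple[str, ...]) -> Phylogeny:
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    children: list[tuple[int, ...]] = [() for _ in range(2 * n - 1)]
    counter = [n]

    def build(node) -> int:
        if isinstance(node, str):
            return index[node]
        a, b = (build(c) for c in node)
        i = counter[0]
        counter[0] += 1
        children[i] = (a, b)
        return i

    build(shape)
    return Phylogeny(labels, children, np.full(2 * n - 1, 0.1))


def enumerate_topologies(labels: list[str]) -> list[Phylogeny]:
    """All rooted bifurcating topologies, in canonical (leaf-insertion) order."""
    labels = sorted(labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 leaves")
    shapes = [(labels[0], labels[1])]
    for leaf in labels[2:]:
        shapes = [s for shape in shapes for s in _insert_leaf(shape, leaf)]
    return [_shape_to_phylogeny(s, tuple(labels)) for s in shapes]


def exhaustive_topology_search(
    table: PillarTable,
    spec: LossModelSpec,
    seed: int = 0,
    n_restarts: int = 5,
    max_leaves: int = 6,
    constraints: dict | None = None,
) -> TopologySearchResult:
    """Fit every rooted topology; the ML topology is the argmax of the lnLs.

    Refuses more than ``max_leaves`` genomes (the enumeration grows as
    (2n-3)!!) unless the guard is raised explicitly.  Ties are broken by the
    canonical Newick string of the topology (stable sort).
    """
    n = len(table.genome_labels)
    if n > max_leaves:
        raise ValueError(
            f"{n} genomes would require {count_rooted_topologies(n)} fits; "
            f"raise max_leaves to override"
        )
    topologies = enumerate_topologies(list(table.genome_labels))
    results = [
        (topo, fit_model(table, topo, spec, constraints=constraints,
                         seed=seed, n_restarts=n_restarts))
        for topo in topologies
    ]
    ranked = sorted(
        results, key=lambda tr: (-tr[1].lnl, tr[0].topology_key())
    )
    return TopologySearchResult(results=ranked, best=ranked[0][1])


def lrt(lnl_nested: float, lnl_full: float, df: int = 1) -> float:
    """Chi-square likelihood-ratio p-value for nested model comparison."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if lnl_full < lnl_nested - 1e-6:
        raise ValueError("full-model lnL below nested-model lnL: models not nested?")
    stat = max(0.0, 2.0 * (lnl_full - lnl_nested))
    return float(chi2.sf(stat, df))


@dataclass
class RetentionSummary:
    """Per-genome fraction of pillars retaining both ohnolog copies."""

    genome_labels: tuple[str, ...]
    fraction_both: np.ndarray
    minimum: float
    maximum: float
    mean: float


def retention_summary(table: PillarTable) -> RetentionSummary:
    codes = derive_observation_codes(table)
    frac = (codes == ObservationCode.BOTH).mean(axis=0)
    return RetentionSummary(
        genome_labels=table.genome_labels,
        fraction_both=frac,
        minimum=float(frac.min()),
        maximum=float(frac.max()),
        mean=float(frac.mean()),
    )
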