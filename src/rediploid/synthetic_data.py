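"""Generators realizing the statistical structure the analyses assume.

Pillar tables are evolved under the four-state loss chain down a phylogeny,
with the hidden subgenome assignment flipping along the pillar order;
codon triplets are evolved along the WGD-then-speciation tree, optionally
with a gene-conversion tract copied from G1 into G2 at a chosen time.
Packaged scenarios bundle inputs mirroring the main analyses (shared vs.
independent polyploidy, a fixation hot-spot, spatially clustered
conversions).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._codon import CodonRates, N_CODONS, decode_codons
from .codon_conversion import CodonModelConfig
from .loss_models import (
    HiddenState,
    LossModelSpec,
    LossParams,
    ModelFlavor,
    build_rate_matrix,
    transition_matrix,
)
from .pillar_io import (
    ABSENT,
    ObservationCode,
    Phylogeny,
    Pillar,
    PillarTable,
    TripletAlignment,
    write_newick,
    write_pillar_table,
    write_triplet_fasta,
)

__all__ = [
    "PillarSimTruth",
    "TripletSimTruth",
    "simulate_pillar_table",
    "simulate_triplet",
    "TripletBranchLengths",
    "scenario",
    "SCENARIOS",
    "stream",
]


def stream(seed: int, label: str) -> np.random.Generator:
    """Label-keyed substream: stable under adding other labels to a bundle."""
    return np.random.default_rng([seed, zlib.crc32(label.encode())])


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("rediploid")
    except Exception:
        return "unknown"


def _result_header(seed: int) -> str:
    return f"# rediploid {_version()} seed={seed}\n"


# ---------------------------------------------------------------------------
# Pillar tables


@dataclass
class PillarSimTruth:
    """Generating truth of a simulated pillar table."""

    tree: Phylogeny
    spec: LossModelSpec
    params: LossParams
    node_states: np.ndarray  # (n_pillars, n_nodes) HiddenState values
    assignments: np.ndarray  # (n_pillars,) assignment-vector index
    seed: int | None
    n_rejected: int
    gamma_by_pillar: np.ndarray | None = None

    def observation_codes(self) -> np.ndarray:
        """(n_pillars, n_genomes) codes implied by leaf states + assignment bits."""
        n_genomes = self.tree.n_leaves
        states = self.node_states[:, :n_genomes]
        bits = (self.assignments[:, None] >> np.arange(n_genomes)[None, :]) & 1
        codes = np.full(states.shape, ObservationCode.BOTH, dtype=np.int8)
        s1 = states == HiddenState.S1.value
        s2 = states == HiddenState.S2.value
        codes[s1 & (bits == 0)] = ObservationCode.TRACK_A_ONLY
        codes[s1 & (bits == 1)] = ObservationCode.TRACK_B_ONLY
        codes[s2 & (bits == 0)] = ObservationCode.TRACK_B_ONLY
        codes[s2 & (bits == 1)] = ObservationCode.TRACK_A_ONLY
        return codes


def _sample_markov(rng, p_rows: np.ndarray, parent_states: np.ndarray) -> np.ndarray:
    """Vectorized categorical draw: next state from p_rows[parent_states]."""
    cum = np.cumsum(p_rows[parent_states], axis=1)
    u = rng.random(len(parent_states))
    return (u[:, None] > cum).sum(axis=1)


def simulate_pillar_table(
    tree: Phylogeny,
    spec: LossModelSpec,
    params: LossParams,
    n_pillars: int,
    seed: int | None = None,
    gamma_by_pillar: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[PillarTable, PillarSimTruth]:
    """Evolve a pillar table under the loss chain with assignment switching.

    Per pillar, the assignment vector follows the per-genome flip chain along
    the pillar order; every pillar starts in state U at the WGD and states
    are sampled down the tree.  ``gamma_by_pillar`` optionally replaces the
    fixation rate per pillar (used to plant fixation hot-spots).  All four
    hidden states retain at least one copy in every genome, so the
    at-least-one-copy filter never rejects; the count is reported as 0.
    """
    if n_pillars < 1:
        raise ValueError("n_pillars must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_genomes = tree.n_leaves
    n_nodes = tree.n_nodes

    # assignment chain
    bits = rng.random((n_pillars, n_genomes)) < 0.5
    flips = rng.random((n_pillars - 1, n_genomes)) < params.switch_prob
    bits[1:] = np.logical_xor.accumulate(
        np.vstack([bits[:1], flips]), axis=0
    )[1:]
    assignments = (bits.astype(np.int64) << np.arange(n_genomes)).sum(axis=1)

    # states down the tree (preorder), possibly with per-pillar gamma groups
    if gamma_by_pillar is None:
        gammas = np.zeros(n_pillars) + params.gamma
    else:
        gammas = np.asarray(gamma_by_pillar, dtype=float)
        if gammas.shape != (n_pillars,):
            raise ValueError("gamma_by_pillar must have one entry per pillar")
    states = np.empty((n_pillars, n_nodes), dtype=np.int8)
    preorder = list(reversed(tree.postorder()))
    permissive = LossModelSpec(ModelFlavor.WGD_bf)  # superset: validates any (eps, gamma)
    for g in np.unique(gammas):
        q = build_rate_matrix(permissive, params.epsilon, float(g))
        idx = np.where(gammas == g)[0]
        parent = np.full(len(idx), HiddenState.U.value, dtype=np.int8)
        p_root = transition_matrix(q, params.branch_lengths[tree.root])
        states[idx, tree.root] = _sample_markov(rng, p_root, parent)
        for node in preorder:
            for child in tree.children[node]:
                p = transition_matrix(q, params.branch_lengths[child])
                states[idx, child] = _sample_markov(rng, p, states[idx, node])

    truth = PillarSimTruth(
        tree=tree,
        spec=spec,
        params=params,
        node_states=states,
        assignments=assignments,
        seed=seed,
        n_rejected=0,
        gamma_by_pillar=None if gamma_by_pillar is None else gammas,
    )
    codes = truth.observation_codes()
    # reject-and-resample filter for all-absent genomes: structurally impossible
    # here (every hidden state keeps >= 1 copy), kept as a guard.
    assert not np.any((codes < 0) | (codes > 2))

    pillars = []
    for i in range(n_pillars):
        tracks = []
        for g, label in enumerate(tree.leaf_labels):
            a = f"{label}_p{i}a"
            b = f"{label}_p{i}b"
            code = codes[i, g]
            if code == ObservationCode.TRACK_A_ONLY:
                b = ABSENT
            elif code == ObservationCode.TRACK_B_ONLY:
                a = ABSENT
            tracks.append((a, b))
        pillars.append(Pillar(index=i, tracks=tuple(tracks)))
    table = PillarTable(genome_labels=tree.leaf_labels, pillars=pillars)
    return table, truth


# ---------------------------------------------------------------------------
# Codon triplets


@dataclass
class TripletBranchLengths:
    """Divergence layout of the (G1, G2, O) triplet, in expected substitutions
    per codon along each lineage segment.

    ``anc``: WGD node to the G1/O speciation; ``g1``/``o``: speciation to the
    present; ``g2``: WGD node to the present.
    """

    anc: float
    g1: float
    o: float
    g2: float


@dataclass
class TripletSimTruth:
    config: CodonModelConfig
    branch_lengths: TripletBranchLengths
    omega: float
    converted: bool
    conversion_time: float | None
    tract_fraction: float | None
    tract_start: int | None
    seed: int | None


def _evolve(rng, rates_p: np.ndarray, seq: np.ndarray) -> np.ndarray:
    cum = np.cumsum(rates_p[seq], axis=1)
    u = rng.random(len(seq))
    return (u[:, None] > cum).sum(axis=1)


def default_codon_config(kappa: float = 2.0) -> CodonModelConfig:
    """Uniform sense-codon frequencies; adequate for simulation studies."""
    return CodonModelConfig(kappa=kappa, pi=np.full(N_CODONS, 1.0 / N_CODONS))


def path_length_for_ks(
    config: CodonModelConfig, ks_target: float, omega: float
) -> float:
    """Total path length (expected subs/codon) giving an expected pairwise Ks."""
    rates = config.rates()
    rho_s = rates.syn_sites / 3.0
    rho_n = rates.nonsyn_sites / 3.0
    syn_fraction = rho_s / (rho_s + omega * rho_n)
    return ks_target * rates.syn_sites / syn_fraction


def simulate_triplet(
    config: CodonModelConfig,
    branch_lengths: TripletBranchLengths,
    n_codons: int,
    omega: float = 0.2,
    conversion: tuple[float, float] | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[TripletAlignment, TripletSimTruth]:
    """Evolve a codon triplet along the WGD-then-speciation tree.

    ``conversion``, if given, is ``(time, tract_fraction)``: at ``time``
    expected-substitution units before the present (within the
    post-speciation interval) a contiguous tract covering ``tract_fraction``
    of the codons is copied from G1 into G2, after which both continue to
    evolve.  The alignment is gap-free by construction.
    """
    if n_codons < 50:
        raise ValueError("n_codons must be >= 50")
    if rng is None:
        rng = np.random.default_rng(seed)
    rates = config.rates()
    q_unit = rates.omega_generator(omega)

    def p_of(t: float) -> np.ndarray:
        # exp(q_unit * t) through the same reversible decomposition
        flux = rates.syn_sites / 3.0 + omega * rates.nonsyn_sites / 3.0
        bs = t * (rates.syn_sites / 3.0) / flux
        bn = t * omega * (rates.nonsyn_sites / 3.0) / flux
        return rates.transition(bs, bn)

    tau, frac = (None, None)
    if conversion is not None:
        tau, frac = conversion
        if not 0.0 < frac <= 1.0:
            raise ValueError("tract fraction must be in (0, 1]")
        if tau < 0 or tau > min(branch_lengths.g1, branch_lengths.g2):
            raise ValueError(
                "conversion time must lie within the post-speciation interval"
            )

    root = rng.choice(N_CODONS, size=n_codons, p=rates.pi)
    spec_node = _evolve(rng, p_of(branch_lengths.anc), root)
    o = _evolve(rng, p_of(branch_lengths.o), spec_node)
    tract_start = None
    if conversion is None:
        g1 = _evolve(rng, p_of(branch_lengths.g1), spec_node)
        g2 = _evolve(rng, p_of(branch_lengths.g2), root)
    else:
        g1_at_tau = _evolve(rng, p_of(branch_lengths.g1 - tau), spec_node)
        g2_at_tau = _evolve(rng, p_of(branch_lengths.g2 - tau), root)
        tract_len = max(1, round(frac * n_codons))
        tract_start = int(rng.integers(0, n_codons - tract_len + 1))
        g2_at_tau = g2_at_tau.copy()
        g2_at_tau[tract_start : tract_start + tract_len] = g1_at_tau[
            tract_start : tract_start + tract_len
        ]
        g1 = _evolve(rng, p_of(tau), g1_at_tau)
        g2 = _evolve(rng, p_of(tau), g2_at_tau)

    aln = TripletAlignment(
        g1=decode_codons(g1), g2=decode_codons(g2), o=decode_codons(o)
    )
    truth = TripletSimTruth(
        config=config,
        branch_lengths=branch_lengths,
        omega=omega,
        converted=conversion is not None,
        conversion_time=tau,
        tract_fraction=frac,
        tract_start=tract_start,
        seed=seed,
    )
    return aln, truth


# ---------------------------------------------------------------------------
# Packaged scenarios


def _two_genome_tree(t_root: float, t_leaf: float = 0.4) -> Phylogeny:
    return Phylogeny(["genomeA", "genomeB"], [(), (), (0, 1)], [t_leaf, t_leaf, t_root])


def _four_genome_tree() -> Phylogeny:
    # ((A,B),(C,D)) with the WGD root branch above
    labels = ["genomeA", "genomeB", "genomeC", "genomeD"]
    children = [(), (), (), (), (0, 1), (2, 3), (4, 5)]
    lengths = [0.3, 0.35, 0.25, 0.4, 0.15, 0.2, 0.3]
    return Phylogeny(labels, children, lengths)


SCENARIOS = ("shared_wgd", "independent_wgd", "fixation_hotspot", "clustered_conversions")


def scenario(name: str, out_dir: str | Path, seed: int = 0, **overrides):
    """Write a self-describing bundle of generated inputs for one analysis.

    ``shared_wgd`` / ``independent_wgd`` — two-genome pillar tables evolved
    with a root branch of length 0.3 vs. 0 (the shared-polyploidy test's
    two hypotheses); ``fixation_hotspot`` — four-genome table with the
    fixation rate elevated in a contiguous 10% pillar block;
    ``clustered_conversions`` — codon triplets with the converted ones
    confined to a contiguous 5% block of pillar positions.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; valid names: {', '.join(SCENARIOS)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {"scenario": name, "seed": seed}

    if name in ("shared_wgd", "independent_wgd"):
        t_root = overrides.get("t_root", 0.3 if name == "shared_wgd" else 0.0)
        n_pillars = overrides.get("n_pillars", 2000)
        tree = _two_genome_tree(t_root)
        spec = LossModelSpec(ModelFlavor.WGD_n)
        params = LossParams(
            epsilon=1.0, gamma=0.0, branch_lengths=tree.lengths, switch_prob=0.01
        )
        table, truth = simulate_pillar_table(
            tree, spec, params, n_pillars, rng=stream(seed, "pillars")
        )
        write_pillar_table(table, out / "pillars.tsv")
        write_newick(tree, out / "tree.nwk")
        _write_truth_states(truth, out / "truth_states.tsv", seed)
        manifest.update(
            t_root=t_root, t_leaf=0.4, n_pillars=n_pillars, model="WGD_n",
            epsilon=1.0, gamma=0.0, switch_prob=0.01,
        )
    elif name == "fixation_hotspot":
        n_pillars = overrides.get("n_pillars", 2000)
        gamma_bg = overrides.get("gamma", 0.1)
        gamma_hot = overrides.get("gamma_hot", 2.0)
        tree = _four_genome_tree()
        spec = LossModelSpec(ModelFlavor.WGD_bf)
        params = LossParams(
            epsilon=0.5, gamma=gamma_bg, branch_lengths=tree.lengths, switch_prob=0.01
        )
        gamma_by_pillar = np.full(n_pillars, gamma_bg)
        hot_start = int(0.45 * n_pillars)
        hot_len = max(1, n_pillars // 10)
        gamma_by_pillar[hot_start : hot_start + hot_len] = gamma_hot
        table, truth = simulate_pillar_table(
            tree, spec, params, n_pillars,
            gamma_by_pillar=gamma_by_pillar, rng=stream(seed, "pillars"),
        )
        write_pillar_table(table, out / "pillars.tsv")
        write_newick(tree, out / "tree.nwk")
        _write_truth_states(truth, out / "truth_states.tsv", seed)
        manifest.update(
            n_pillars=n_pillars, model="WGD_bf", epsilon=0.5, gamma=gamma_bg,
            gamma_hot=gamma_hot, hot_start=hot_start, hot_len=hot_len,
            switch_prob=0.01,
        )
    else:  # clustered_conversions
        n_pillars = overrides.get("n_pillars", 2000)
        n_triplets = overrides.get("n_triplets", 40)
        n_converted = overrides.get("n_converted", 10)
        n_codons = overrides.get("n_codons", 300)
        config = default_codon_config()
        ks_bg = overrides.get("ks_background", 0.3)
        ks_spec = overrides.get("ks_speciation", 0.1)
        t_wgd = path_length_for_ks(config, ks_bg, 0.2) / 2.0
        t_spec = path_length_for_ks(config, ks_spec, 0.2) / 2.0
        bl = TripletBranchLengths(anc=t_wgd - t_spec, g1=t_spec, o=t_spec, g2=t_wgd)
        block_len = max(1, n_pillars // 20)  # contiguous 5% block
        block_start = int(0.6 * n_pillars)
        rng = stream(seed, "positions")
        conv_pos = np.sort(
            rng.choice(np.arange(block_start, block_start + block_len), n_converted, replace=False)
        )
        other = np.setdiff1d(np.arange(n_pillars), conv_pos)
        null_pos = np.sort(rng.choice(other, n_triplets - n_converted, replace=False))
        rows = []
        tdir = out / "triplets"
        tdir.mkdir(exist_ok=True)
        for kind, positions in (("conv", conv_pos), ("null", null_pos)):
            for pos in positions:
                conv = (0.0, 1.0) if kind == "conv" else None
                aln, truth = simulate_triplet(
                    config, bl, n_codons, omega=0.2, conversion=conv,
                    rng=stream(seed, f"triplet_{pos}"),
                )
                fname = f"pillar{pos:05d}.fasta"
                write_triplet_fasta(aln, tdir / fname, stem=f"pillar{pos:05d}")
                rows.append((int(pos), kind == "conv", fname))
        rows.sort()
        with (out / "truth_triplets.tsv").open("w") as fh:
            fh.write(_result_header(seed))
            fh.write("pillar\tconverted\tfasta\n")
            for pos, conv_flag, fname in rows:
                fh.write(f"{pos}\t{int(conv_flag)}\ttriplets/{fname}\n")
        manifest.update(
            n_pillars=n_pillars, n_triplets=n_triplets, n_converted=n_converted,
            n_codons=n_codons, ks_background=ks_bg, ks_speciation=ks_spec,
            block_start=block_start, block_len=block_len, omega=0.2,
        )

    with (out / "manifest.txt").open("w") as fh:
        for key in sorted(manifest):
            fh.write(f"{key}={manifest[key]}\n")
    return out


def _write_truth_states(truth: PillarSimTruth, path: Path, seed: int) -> None:
    names = [HiddenState(v).name for v in range(4)]
    with Path(path).open("w") as fh:
        fh.write(_result_header(seed))
        labels = truth.tree.leaf_labels
        fh.write("pillar\tassignment\t" + "\t".join(f"state_{g}" for g in labels) + "\n")
        for i in range(truth.node_states.shape[0]):
            leaf_states = [names[s] for s in truth.node_states[i, : len(labels)]]
            fh.write(f"{i}\t{int(truth.assignments[i])}\t" + "\t".join(leaf_states) + "\n")
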