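"""Detection of interlocus gene conversion from ohnolog/ortholog triplets.

For an ohnolog pair (G1, G2) with a syntenic ortholog O of G1 in a close
polyploid relative: G1 and O diverged at the (recent) speciation while G1
and G2 diverged at the (ancient) WGD.  Without conversion the nonsynonymous
divergence on O's branch should therefore be below G2's.  A codon model
with branch-specific synonymous and nonsynonymous rates is fitted to the
unrooted 3-taxon star tree; when Ka_O exceeds both Ka_G1 and Ka_G2 the
triplet is a conversion candidate and a 1-df likelihood-ratio test against
the constrained model with Ka_O = Ka_G2 gives its significance.  Spatial
clustering of significant events along the ancestral pillar order is tested
by randomization, and near-zero paralog Ks flags the conversions as recent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from ._codon import CodonRates, N_CODONS, encode_codons, f3x4_frequencies
from .loss_models import AssignmentPosterior
from .pillar_io import ObservationCode, PillarTable, TripletAlignment, derive_observation_codes

__all__ = [
    "CodonModelConfig",
    "TripletFit",
    "ConversionResult",
    "PairKs",
    "ClusterTestResult",
    "fit_triplet_codon_model",
    "conversion_test",
    "pairwise_ks",
    "select_triplets",
    "conversion_clustering_test",
    "conversion_results_table",
]

MIN_CODONS = 50
_BRANCHES = ("G1", "G2", "O")


@dataclass
class CodonModelConfig:
    """Codon-model settings: transition/transversion ratio and codon frequencies."""

    kappa: float
    pi: np.ndarray  # 61-entry simplex over sense codons

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.pi.shape != (N_CODONS,) or abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must be a 61-entry simplex")

    def rates(self) -> CodonRates:
        return CodonRates(self.kappa, self.pi)


@dataclass
class TripletFit:
    """ML fit of the branch-rates codon model to a (G1, G2, O) triplet."""

    ka: dict[str, float]  # branch-specific Ka per gene
    ks: dict[str, float]  # branch-specific Ks per gene
    bs: dict[str, float]  # expected synonymous substitutions per codon
    bn: dict[str, float]  # expected nonsynonymous substitutions per codon
    lnl: float
    config: CodonModelConfig
    n_codons: int
    converged: bool


@dataclass
class ConversionResult:
    """Outcome of the triplet gene-conversion test."""

    fit: TripletFit
    candidate: bool  # Ka_O > Ka_G1 and Ka_O > Ka_G2
    lnl_free: float
    lnl_constrained: float | None = None
    statistic: float | None = None
    p_value: float | None = None
    significant: bool = False


@dataclass
class PairKs:
    """Pairwise synonymous divergence of an aligned paralog pair."""

    ks: float
    ka: float
    lnl: float
    c: float | None = None  # orthology confidence of the pair's pillar, if known


@dataclass
class ClusterTestResult:
    """Randomization test for spatial clustering of conversion events."""

    observed_mean_distance: float
    null_mean_distances: np.ndarray
    n_randomizations: int
    p_value: float


# ---------------------------------------------------------------------------
# Likelihood machinery


def _site_patterns(cols: list[tuple[str, ...]]) -> tuple[np.ndarray, np.ndarray]:
    idx = np.array([[encode_codons(c)[0] for c in col] for col in cols])
    patterns, counts = np.unique(idx, axis=0, return_counts=True)
    return patterns, counts.astype(float)


def _star_loglik(
    rates: CodonRates, bs: np.ndarray, bn: np.ndarray, patterns: np.ndarray, counts: np.ndarray
) -> float:
    """lnL of the 3-taxon star tree; the unobserved center carries the stationary pi."""
    acc = np.broadcast_to(rates.pi[:, None], (N_CODONS, len(patterns))).copy()
    for b in range(patterns.shape[1]):
        p = rates.transition(bs[b], bn[b])
        acc *= p[:, patterns[:, b]]
    site = acc.sum(axis=0)
    if np.any(site <= 0):
        return -np.inf
    return float(counts @ np.log(site))


def _init_branch_lengths(patterns: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Crude per-branch divergence from pairwise p-distances (3-point formula)."""
    n = counts.sum()
    d = np.zeros(3)
    pairs = [(0, 1), (0, 2), (1, 2)]
    pd = {}
    for a, b in pairs:
        diff = (patterns[:, a] != patterns[:, b]) @ counts / n
        pd[(a, b)] = max(-np.log(max(1.0 - 1.4 * diff, 0.05)), 1e-3)
    d[0] = max((pd[(0, 1)] + pd[(0, 2)] - pd[(1, 2)]) / 2, 1e-3)
    d[1] = max((pd[(0, 1)] + pd[(1, 2)] - pd[(0, 2)]) / 2, 1e-3)
    d[2] = max((pd[(0, 2)] + pd[(1, 2)] - pd[(0, 1)]) / 2, 1e-3)
    return d


def _validated_columns(alignment: TripletAlignment, min_codons: int) -> list:
    cols = alignment.ungapped_codon_columns()
    if len(cols) < min_codons:
        raise ValueError(
            f"alignment has {len(cols)} ungapped codons; at least {min_codons} required"
        )
    return cols


def fit_triplet_codon_model(
    alignment: TripletAlignment,
    min_codons: int = MIN_CODONS,
    constrain_o_eq_g2: bool = False,
    config: CodonModelConfig | None = None,
) -> TripletFit:
    """ML fit of the codon model with per-branch syn/nonsyn rates.

    Branch order (G1, G2, O).  ``constrain_o_eq_g2`` shares one
    nonsynonymous rate between the O and G2 branches (the conversion-test
    null); synonymous rates stay free.  ``config`` defaults to kappa fitted
    by ML and F3x4 frequencies from the triplet itself.
    """
    cols = _validated_columns(alignment, min_codons)
    patterns, counts = _site_patterns(cols)
    pi = (
        config.pi
        if config is not None
        else f3x4_frequencies([alignment.g1, alignment.g2, alignment.o])
    )
    fit_kappa = config is None
    d = _init_branch_lengths(patterns, counts)
    bs0 = np.maximum(0.7 * d, 1e-3)
    bn0 = np.maximum(0.3 * d, 1e-3)

    # free params: [log kappa?] + log bs (3) + log bn (3 or 2 when constrained)
    nbn = 2 if constrain_o_eq_g2 else 3

    def unpack(x):
        k = 0
        if fit_kappa:
            kappa = np.exp(x[0])
            k = 1
        else:
            kappa = config.kappa
        bs = np.exp(x[k : k + 3])
        bn_raw = np.exp(x[k + 3 : k + 3 + nbn])
        if constrain_o_eq_g2:
            bn = np.array([bn_raw[0], bn_raw[1], bn_raw[1]])
        else:
            bn = bn_raw
        return kappa, bs, bn

    def neg(x):
        kappa, bs, bn = unpack(x)
        rates = CodonRates(kappa, pi)
        return -_star_loglik(rates, bs, bn, patterns, counts)

    x0 = []
    if fit_kappa:
        x0.append(np.log(2.0))
    x0 += list(np.log(bs0))
    bn_init = bn0 if not constrain_o_eq_g2 else np.array([bn0[0], (bn0[1] + bn0[2]) / 2])
    x0 += list(np.log(bn_init))
    x0 = np.array(x0)
    lo, hi = np.log(1e-6), np.log(20.0)
    bounds = ([(np.log(0.1), np.log(20.0))] if fit_kappa else []) + [(lo, hi)] * (3 + nbn)
    res = minimize(neg, x0, method="L-BFGS-B", bounds=bounds, options={"maxiter": 500})
    kappa, bs, bn = unpack(res.x)
    rates = CodonRates(kappa, pi)
    return TripletFit(
        ka={g: rates.ka(bn[i]) for i, g in enumerate(_BRANCHES)},
        ks={g: rates.ks(bs[i]) for i, g in enumerate(_BRANCHES)},
        bs={g: float(bs[i]) for i, g in enumerate(_BRANCHES)},
        bn={g: float(bn[i]) for i, g in enumerate(_BRANCHES)},
        lnl=float(-res.fun),
        config=CodonModelConfig(kappa=kappa, pi=pi),
        n_codons=len(cols),
        converged=bool(res.success),
    )


def conversion_test(
    alignment: TripletAlignment,
    min_codons: int = MIN_CODONS,
    alpha: float = 0.05,
) -> ConversionResult:
    """Gene-conversion test: Ka_O > Ka_G1, Ka_G2 triggers a 1-df LRT of Ka_O = Ka_G2."""
    free = fit_triplet_codon_model(alignment, min_codons=min_codons)
    candidate = free.ka["O"] > free.ka["G1"] and free.ka["O"] > free.ka["G2"]
    result = ConversionResult(fit=free, candidate=candidate, lnl_free=free.lnl)
    if not candidate:
        return result
    constrained = fit_triplet_codon_model(
        alignment, min_codons=min_codons, constrain_o_eq_g2=True
    )
    stat = max(0.0, 2.0 * (free.lnl - constrained.lnl))
    p = float(chi2.sf(stat, df=1))
    result.lnl_constrained = constrained.lnl
    result.statistic = stat
    result.p_value = p
    result.significant = p <= alpha
    return result


def pairwise_ks(
    seq1: str,
    seq2: str,
    min_codons: int = MIN_CODONS,
    c: float | None = None,
) -> PairKs:
    """Pairwise Ka/Ks of two aligned coding sequences under the same codon family."""
    if len(seq1) != len(seq2) or len(seq1) % 3:
        raise ValueError("sequences must be aligned with length a multiple of 3")
    cols = []
    for k in range(0, len(seq1), 3):
        a, b = seq1[k : k + 3].upper(), seq2[k : k + 3].upper()
        if "-" not in a and "-" not in b:
            cols.append((a, b))
    if len(cols) < min_codons:
        raise ValueError(
            f"alignment has {len(cols)} ungapped codons; at least {min_codons} required"
        )
    patterns, counts = _site_patterns(cols)
    pi = f3x4_frequencies([seq1, seq2])
    n = counts.sum()
    diff = (patterns[:, 0] != patterns[:, 1]) @ counts / n
    t0 = max(-np.log(max(1.0 - 1.4 * diff, 0.05)), 1e-3)

    def neg(x):
        kappa = np.exp(x[0])
        bs, bn = np.exp(x[1]), np.exp(x[2])
        rates = CodonRates(kappa, pi)
        p = rates.transition(bs, bn)
        site = pi[patterns[:, 0]] * p[patterns[:, 0], patterns[:, 1]]
        if np.any(site <= 0):
            return np.inf
        return -float(counts @ np.log(site))

    x0 = np.array([np.log(2.0), np.log(max(0.7 * t0, 1e-3)), np.log(max(0.3 * t0, 1e-3))])
    bounds = [(np.log(0.1), np.log(20.0))] + [(np.log(1e-6), np.log(20.0))] * 2
    res = minimize(neg, x0, method="L-BFGS-B", bounds=bounds, options={"maxiter": 300})
    kappa, bs, bn = np.exp(res.x)
    rates = CodonRates(kappa, pi)
    return PairKs(ks=rates.ks(bs), ka=rates.ka(bn), lnl=float(-res.fun), c=c)


def select_triplets(
    table: PillarTable,
    confidences: AssignmentPosterior,
    c_min: float,
    reference_genome: str,
    relative_genome: str,
) -> list[tuple[int, str, str, str]]:
    """Pillars eligible for the conversion test, as (pillar, G1, G2, O) gene ids.

    Keeps pillars where the reference genome retains both copies and the
    relative genome's copy syntenic-orthologous to G1 (same subgenome under
    the modal assignment) is present, with assignment confidence >= c_min.
    """
    labels = list(table.genome_labels)
    if reference_genome not in labels or relative_genome not in labels:
        raise ValueError("reference and relative genomes must appear in the table")
    post_labels = list(confidences.genome_labels)
    ref_bit_pos = post_labels.index(reference_genome)
    rel_bit_pos = post_labels.index(relative_genome)
    g_ref = labels.index(reference_genome)
    g_rel = labels.index(relative_genome)
    codes = derive_observation_codes(table)
    out: list[tuple[int, str, str, str]] = []
    for i, pillar in enumerate(table.pillars):
        if codes[i, g_ref] != ObservationCode.BOTH:
            continue
        if confidences.c[i] < c_min:
            continue
        vec = int(confidences.modal_assignment[i])
        ref_bit = (vec >> ref_bit_pos) & 1
        rel_bit = (vec >> rel_bit_pos) & 1
        g1, g2 = pillar.tracks[g_ref]
        # O is the relative's track on G1's subgenome: same track letter when the
        # two genomes carry the same assignment bit, the opposite letter otherwise.
        rel_a, rel_b = pillar.tracks[g_rel]
        o = rel_a if ref_bit == rel_bit else rel_b
        if o == "-":
            continue
        out.append((pillar.index, g1, g2, o))
    return out


def conversion_results_table(
    results: list[ConversionResult],
    pillars: list[int],
    ks: list[float] | None = None,
    n_pillars: int | None = None,
):
    """Per-triplet results table (the plotting/reporting output).

    One row per tested triplet: pillar, scaled position, branch Ka values,
    candidate flag, raw p, significance at p <= 0.05, paralog Ks if
    supplied, and supplementary Benjamini-Hochberg q-values over the tested
    candidates (the significance calls themselves use the raw p).
    """
    import pandas as pd
    from scipy.stats import false_discovery_control

    if len(results) != len(pillars):
        raise ValueError("one pillar position per result is required")
    denom = (n_pillars - 1) if n_pillars and n_pillars > 1 else max(max(pillars), 1)
    p = np.array(
        [r.p_value if r.p_value is not None else np.nan for r in results]
    )
    q = np.full(len(p), np.nan)
    tested = ~np.isnan(p)
    if tested.any():
        q[tested] = false_discovery_control(p[tested], method="bh")
    return pd.DataFrame(
        {
            "pillar": pillars,
            "scaled_pos": np.asarray(pillars, dtype=float) / denom,
            "ka_o": [r.fit.ka["O"] for r in results],
            "ka_g1": [r.fit.ka["G1"] for r in results],
            "ka_g2": [r.fit.ka["G2"] for r in results],
            "candidate": [r.candidate for r in results],
            "p": p,
            "q_bh": q,
            "significant": [r.significant for r in results],
            "ks": ks if ks is not None else np.full(len(p), np.nan),
        }
    )


def conversion_clustering_test(
    event_positions: np.ndarray,
    n_pillars: int,
    n_rand: int = 1000,
    seed: int | None = None,
) -> ClusterTestResult:
    """Randomization test: are conversion events closer together than uniform?

    The statistic is the mean, over events, of the pillar-index distance to
    the nearest other event.  Each randomization draws the same number of
    distinct pillar positions uniformly; the p-value is the add-one-corrected
    proportion of randomizations with a smaller mean distance.
    """
    pos = np.asarray(sorted(set(int(p) for p in event_positions)))
    if len(pos) < 2:
        raise ValueError("clustering undefined for fewer than 2 events")
    if pos[0] < 0 or pos[-1] >= n_pillars:
        raise ValueError("event positions must lie within [0, n_pillars)")

    def mean_nn(sorted_pos: np.ndarray) -> float:
        gaps = np.diff(sorted_pos)
        left = np.concatenate(([np.inf], gaps))
        right = np.concatenate((gaps, [np.inf]))
        return float(np.minimum(left, right).mean())

    observed = mean_nn(pos)
    rng = np.random.default_rng(seed)
    null = np.empty(n_rand)
    for r in range(n_rand):
        draw = rng.choice(n_pillars, size=len(pos), replace=False)
        draw.sort()
        null[r] = mean_nn(draw)
    p = (float(np.sum(null < observed)) + 1.0) / (n_rand + 1.0)
    return ClusterTestResult(
        observed_mean_distance=observed,
        null_mean_distances=null,
        n_randomizations=n_rand,
        p_value=p,
    )
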