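"""GY94-style codon substitution machinery.

Codon-level CTMC with single-nucleotide steps, a transition/transversion
ratio ``kappa``, target-codon frequencies ``pi`` (typically F3x4-estimated)
and separate synonymous / nonsynonymous flow scalings per branch.  The two
flow components are normalized so that a branch parameterized by
``(bs, bn)`` accumulates ``bs`` expected synonymous and ``bn`` expected
nonsynonymous substitutions per codon; Ka and Ks then follow by dividing by
the nonsynonymous / synonymous site counts per codon (neutral-flux
proportions times 3).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

_NUCS = "ACGT"
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@lru_cache(maxsize=1)
def _code_tables():
    table = CodonTable.unambiguous_dna_by_id[1]
    stops = set(table.stop_codons)
    codons = [
        a + b + c
        for a in _NUCS
        for b in _NUCS
        for c in _NUCS
        if a + b + c not in stops
    ]
    index = {c: i for i, c in enumerate(codons)}
    aa = [table.forward_table[c] for c in codons]
    n = len(codons)
    single = np.zeros((n, n), dtype=bool)  # one-nucleotide neighbors
    is_ts = np.zeros((n, n), dtype=bool)
    is_syn = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(codons):
        for j, cj in enumerate(codons):
            if i == j:
                continue
            diffs = [(x, y) for x, y in zip(ci, cj) if x != y]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            is_ts[i, j] = diffs[0] in _TRANSITIONS
            is_syn[i, j] = aa[i] == aa[j]
    return codons, index, single, is_ts, is_syn


SENSE_CODONS: tuple[str, ...] = tuple(_code_tables()[0])
N_CODONS = len(SENSE_CODONS)
CODON_INDEX: dict[str, int] = dict(_code_tables()[1])


def encode_codons(seq: str) -> np.ndarray:
    """Codon-index array for an ungapped coding sequence (error on stops)."""
    if len(seq) % 3:
        raise ValueError("sequence length must be a multiple of 3")
    out = np.empty(len(seq) // 3, dtype=np.int64)
    for k in range(0, len(seq), 3):
        codon = seq[k : k + 3].upper()
        if codon not in CODON_INDEX:
            raise ValueError(f"invalid or stop codon {codon!r} at position {k}")
        out[k // 3] = CODON_INDEX[codon]
    return out


def decode_codons(idx: np.ndarray) -> str:
    return "".join(SENSE_CODONS[i] for i in idx)


def f3x4_frequencies(seqs: list[str], pseudocount: float = 0.5) -> np.ndarray:
    """F3x4 codon frequencies over the sense codons, from pooled sequences."""
    counts = np.full((3, 4), pseudocount)
    nuc_index = {n: k for k, n in enumerate(_NUCS)}
    for seq in seqs:
        s = seq.upper()
        for k in range(0, len(s) - len(s) % 3, 3):
            codon = s[k : k + 3]
            if "-" in codon:
                continue
            for pos, nt in enumerate(codon):
                if nt in nuc_index:
                    counts[pos, nuc_index[nt]] += 1
    pos_freq = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freq[0, "ACGT".index(c[0])]
            * pos_freq[1, "ACGT".index(c[1])]
            * pos_freq[2, "ACGT".index(c[2])]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()


class CodonRates:
    """Rate components and site counts for a given (kappa, pi).

    ``s_tilde``/``n_tilde`` are the synonymous / nonsynonymous generator
    parts scaled so that one unit of either flow is one expected event per
    codon at stationarity.  ``syn_sites``/``nonsyn_sites`` are sites per
    codon from neutral flux proportions (3 * rho).
    """

    def __init__(self, kappa: float, pi: np.ndarray) -> None:
        if kappa <= 0:
            raise ValueError("kappa must be positive")
        pi = np.asarray(pi, dtype=float)
        if pi.shape != (N_CODONS,) or np.any(pi <= 0):
            raise ValueError("pi must be a positive 61-entry simplex")
        pi = pi / pi.sum()
        _, _, single, is_ts, is_syn = _code_tables()
        base = np.where(single, np.where(is_ts, kappa, 1.0), 0.0) * pi[None, :]
        s_raw = np.where(is_syn, base, 0.0)
        n_raw = np.where(single & ~is_syn, base, 0.0)
        flux_s = float(pi @ s_raw.sum(axis=1))
        flux_n = float(pi @ n_raw.sum(axis=1))
        self.kappa = kappa
        self.pi = pi
        self.s_tilde = s_raw / flux_s
        self.n_tilde = n_raw / flux_n
        rho_s = flux_s / (flux_s + flux_n)
        self.syn_sites = 3.0 * rho_s
        self.nonsyn_sites = 3.0 * (1.0 - rho_s)

    def generator(self, bs: float, bn: float) -> np.ndarray:
        """Generator accumulating bs syn + bn nonsyn substitutions per codon per unit time."""
        q = bs * self.s_tilde + bn * self.n_tilde
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def transition(self, bs: float, bn: float) -> np.ndarray:
        """exp(generator) via symmetric eigendecomposition (the chain is reversible)."""
        q = self.generator(bs, bn)
        sq = np.sqrt(self.pi)
        b = (sq[:, None] * q) / sq[None, :]
        b = 0.5 * (b + b.T)  # symmetric up to rounding
        w, v = np.linalg.eigh(b)
        p = (v * np.exp(w)) @ v.T
        p = (p / sq[:, None]) * sq[None, :]
        # eigen-roundoff can push tiny entries slightly negative; floor them at
        # a positive value so log-likelihoods stay finite and differentiable
        np.clip(p, 1e-18, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def omega_generator(self, omega: float) -> np.ndarray:
        """Generator at fixed dN/dS, normalized to 1 expected substitution per codon."""
        flux = self.syn_sites / 3.0 + omega * self.nonsyn_sites / 3.0
        return self.generator(
            (self.syn_sites / 3.0) / flux, omega * (self.nonsyn_sites / 3.0) / flux
        )

    def ka(self, bn: float) -> float:
        return bn / self.nonsyn_sites

    def ks(self, bs: float) -> float:
        return bs / self.syn_sites
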