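"""Data model and I/O for pillar tables, phylogenies and codon triplets.

A *pillar* is one ancestral, pre-WGD gene position tracked as up to two
homoeologous copies ("tracks") in each descendant polyploid genome.  Pillar
tables are the observation data for the ohnolog-loss models: each genome at
each pillar either retains both copies or exactly one of them (pillars are
filtered upstream so that every genome retains at least one copy).

File dialects:

* pillar tables — TSV with a first column ``pillar`` (0-based consecutive
  index) followed by two columns ``<genome>.a`` and ``<genome>.b`` per
  genome; the absence marker is ``-``;
* trees — Newick, rooted and strictly bifurcating; the root edge length, if
  present, is the "root branch" from the WGD event to the first speciation;
* triplet alignments — aligned FASTA, gap character ``-``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

ABSENT = "-"

__all__ = [
    "ABSENT",
    "ObservationCode",
    "Pillar",
    "PillarTable",
    "Phylogeny",
    "TripletAlignment",
    "read_pillar_table",
    "write_pillar_table",
    "derive_observation_codes",
    "read_newick",
    "write_newick",
    "read_triplet_fasta",
    "write_triplet_fasta",
]


class ObservationCode(IntEnum):
    """Per-genome, per-pillar retention pattern.

    ``BOTH`` — both tracks retained; ``TRACK_A_ONLY`` / ``TRACK_B_ONLY`` —
    a single surviving copy.  An all-absent code cannot occur: pillar tables
    only contain pillars retained in at least one copy in every genome.
    """

    BOTH = 0
    TRACK_A_ONLY = 1
    TRACK_B_ONLY = 2


@dataclass(frozen=True)
class Pillar:
    """One ancestral locus: per genome, the two track slots (gene id or ``-``)."""

    index: int
    tracks: tuple[tuple[str, str], ...]  # one (track_a, track_b) per genome


@dataclass
class PillarTable:
    """Ordered pillars with two-track gene presence per genome.

    Invariants (checked by :meth:`validate`): pillar indices are consecutive
    from 0; every pillar retains at least one copy in every genome; at least
    two genomes.
    """

    genome_labels: tuple[str, ...]
    pillars: list[Pillar] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genome_labels = tuple(self.genome_labels)
        self.validate()

    @property
    def n_genomes(self) -> int:
        return len(self.genome_labels)

    @property
    def n_pillars(self) -> int:
        return len(self.pillars)

    def validate(self) -> None:
        if len(self.genome_labels) < 2:
            raise ValueError("a pillar table needs at least two genomes")
        if len(set(self.genome_labels)) != len(self.genome_labels):
            raise ValueError("duplicate genome labels")
        for k, pillar in enumerate(self.pillars):
            if pillar.index != k:
                raise ValueError(
                    f"pillar indices must be consecutive from 0; "
                    f"found {pillar.index} at position {k}"
                )
            if len(pillar.tracks) != self.n_genomes:
                raise ValueError(f"pillar {k}: wrong number of genome slots")
            for label, (a, b) in zip(self.genome_labels, pillar.tracks):
                if a == ABSENT and b == ABSENT:
                    raise ValueError(
                        f"pillar {pillar.index}, genome {label!r}: both tracks "
                        "absent (pillars must be retained in at least one copy "
                        "in every genome)"
                    )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PillarTable):
            return NotImplemented
        return (
            self.genome_labels == other.genome_labels
            and self.pillars == other.pillars
        )


def derive_observation_codes(table: PillarTable) -> np.ndarray:
    """Observation codes, shape ``(n_pillars, n_genomes)`` of :class:`ObservationCode`.

    BOTH iff both tracks present, TRACK_A_ONLY iff only track a, else
    TRACK_B_ONLY.  Total by the table invariant.
    """
    codes = np.empty((table.n_pillars, table.n_genomes), dtype=np.int8)
    for i, pillar in enumerate(table.pillars):
        for g, (a, b) in enumerate(pillar.tracks):
            if a != ABSENT and b != ABSENT:
                codes[i, g] = ObservationCode.BOTH
            elif a != ABSENT:
                codes[i, g] = ObservationCode.TRACK_A_ONLY
            else:
                codes[i, g] = ObservationCode.TRACK_B_ONLY
    return codes


def read_pillar_table(path: str | Path) -> PillarTable:
    """Read a pillar-table TSV (see module docstring for the dialect)."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header[0] != "pillar" or (len(header) - 1) % 2 != 0:
        raise ValueError(f"{path}:1: malformed header")
    labels: list[str] = []
    for j in range(1, len(header), 2):
        a, b = header[j], header[j + 1]
        if not (a.endswith(".a") and b.endswith(".b") and a[:-2] == b[:-2]):
            raise ValueError(f"{path}:1: malformed genome columns {a!r}/{b!r}")
        labels.append(a[:-2])
    n_cols = 1 + 2 * len(labels)
    pillars: list[Pillar] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != n_cols:
            raise ValueError(
                f"{path}:{lineno}: expected {n_cols} columns, got {len(fields)}"
            )
        try:
            idx = int(fields[0])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad pillar index {fields[0]!r}") from exc
        tracks = tuple(
            (fields[1 + 2 * g], fields[2 + 2 * g]) for g in range(len(labels))
        )
        pillars.append(Pillar(index=idx, tracks=tracks))
    return PillarTable(genome_labels=tuple(labels), pillars=pillars)


def write_pillar_table(table: PillarTable, path: str | Path) -> None:
    """Write the TSV dialect; bit-stable for identical input."""
    path = Path(path)
    cols = ["pillar"]
    for label in table.genome_labels:
        cols += [f"{label}.a", f"{label}.b"]
    out = ["\t".join(cols)]
    for pillar in table.pillars:
        row = [str(pillar.index)]
        for a, b in pillar.tracks:
            row += [a, b]
        out.append("\t".join(row))
    path.write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Phylogenies


class Phylogeny:
    """Rooted, strictly bifurcating tree with the WGD event above the root node.

    The root node is the first speciation; the WGD sits above it at distance
    ``root_length`` (the "root branch").  Internally nodes are indexed
    0..2n-2 with leaves first in ``leaf_labels`` order; ``children[i]`` is
    empty for leaves; ``lengths[i]`` is the length of the edge above node i
    (for the root node, ``lengths[root] == root_length``).  Branch lengths
    are in expected-loss units (the base loss rate is fixed to 1).
    """

    def __init__(
        self,
        leaf_labels: Sequence[str],
        children: Sequence[tuple[int, ...]],
        lengths: Sequence[float],
    ) -> None:
        self.leaf_labels = tuple(leaf_labels)
        self.children = tuple(tuple(c) for c in children)
        self.lengths = np.asarray(lengths, dtype=float).copy()
        n = len(self.leaf_labels)
        if len(self.children) != 2 * n - 1 or len(self.lengths) != 2 * n - 1:
            raise ValueError("inconsistent node arrays")
        for i, ch in enumerate(self.children):
            if i < n and ch:
                raise ValueError("leaf with children")
            if i >= n and len(ch) != 2:
                raise ValueError("tree must be strictly bifurcating")
        if np.any(self.lengths < 0):
            raise ValueError("branch lengths must be non-negative")
        self.root = 2 * n - 2

    # -- structural helpers -------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def root_length(self) -> float:
        return float(self.lengths[self.root])

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        order.reverse()
        return order

    def with_lengths(self, lengths: Sequence[float]) -> "Phylogeny":
        return Phylogeny(self.leaf_labels, self.children, lengths)

    def topology_key(self) -> str:
        """Canonical Newick string without branch lengths (identifies the topology)."""

        def label(node: int) -> str:
            if node < self.n_leaves:
                return self.leaf_labels[node]
            parts = sorted(label(c) for c in self.children[node])
            return "(" + ",".join(parts) + ")"

        return label(self.root) + ";"

    # -- Newick conversion ---------------------------------------------------

    def to_newick(self) -> str:
        def render(node: int) -> str:
            if node < self.n_leaves:
                return f"{self.leaf_labels[node]}:{self.lengths[node]:.10g}"
            inner = ",".join(render(c) for c in self.children[node])
            return f"({inner}):{self.lengths[node]:.10g}"

        return render(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
        seed = tree.seed_node
        if len(seed.child_nodes()) != 2:
            raise ValueError(
                "unsupported tree structure: root must have exactly two children "
                "(rooted, bifurcating)"
            )
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        leaf_labels = sorted(leaves)
        if len(set(leaf_labels)) != len(leaf_labels):
            raise ValueError("duplicate leaf labels")
        index = {lab: i for i, lab in enumerate(leaf_labels)}
        n = len(leaf_labels)
        children: list[tuple[int, ...]] = [() for _ in range(2 * n - 1)]
        lengths = np.zeros(2 * n - 1)
        next_internal = [n]

        def build(node: dendropy.Node) -> int:
            kids = node.child_nodes()
            if not kids:
                i = index[node.taxon.label]
            elif len(kids) == 2:
                a, b = (build(k) for k in kids)
                i = next_internal[0]
                next_internal[0] += 1
                children[i] = (a, b)
            else:
                raise ValueError("unsupported tree structure: multifurcation")
            lengths[i] = node.edge.length if node.edge.length is not None else 0.0
            return i

        root_idx = build(seed)
        assert root_idx == 2 * n - 2
        return cls(leaf_labels, children, lengths)


def read_newick(path: str | Path) -> Phylogeny:
    """Read a rooted bifurcating Newick tree (root edge length = root branch)."""
    return Phylogeny.from_newick(Path(path).read_text(encoding="utf-8"))


def write_newick(tree: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Codon triplet alignments

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class TripletAlignment:
    """Aligned coding sequences of ohnologs G1, G2 and ortholog O.

    G1 and G2 are the two WGD paralogs in one genome; O is the syntenic
    ortholog of G1 in a close polyploid relative.  Lengths are equal and a
    multiple of 3; gap character ``-``.
    """

    g1: str
    g2: str
    o: str

    def __post_init__(self) -> None:
        seqs = (self.g1, self.g2, self.o)
        if len({len(s) for s in seqs}) != 1:
            raise ValueError("aligned sequences must have equal length")
        if len(self.g1) % 3 != 0:
            raise ValueError("aligned length must be a multiple of 3")
        for name, seq in zip(("G1", "G2", "O"), seqs):
            for k in range(0, len(seq) - 3, 3):
                codon = seq[k : k + 3]
                if "-" not in codon and codon.upper() in _STOPS:
                    raise ValueError(f"{name}: internal stop codon at position {k}")

    @property
    def n_columns(self) -> int:
        return len(self.g1) // 3

    def ungapped_codon_columns(self) -> list[tuple[str, str, str]]:
        """Codon columns with no gap in any sequence (listwise deletion)."""
        cols = []
        for k in range(0, len(self.g1), 3):
            c = (self.g1[k : k + 3], self.g2[k : k + 3], self.o[k : k + 3])
            if not any("-" in x for x in c):
                cols.append(tuple(x.upper() for x in c))
        return cols


def read_triplet_fasta(path: str | Path) -> TripletAlignment:
    """Read a 3-record aligned FASTA with ids suffixed ``_G1``/``_G2``/``_O``."""
    from Bio import SeqIO

    records = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
    if len(records) != 3:
        raise ValueError(f"{path}: expected exactly 3 records")
    by_role: dict[str, str] = {}
    for rid, seq in records.items():
        for role in ("G1", "G2", "O"):
            if rid.endswith("_" + role):
                by_role[role] = seq
    if set(by_role) != {"G1", "G2", "O"}:
        raise ValueError(f"{path}: record ids must end in _G1, _G2, _O")
    return TripletAlignment(g1=by_role["G1"], g2=by_role["G2"], o=by_role["O"])


def write_triplet_fasta(
    aln: TripletAlignment, path: str | Path, stem: str = "triplet"
) -> None:
    lines = []
    for role, seq in (("G1", aln.g1), ("G2", aln.g2), ("O", aln.o)):
        lines.append(f">{stem}_{role}")
        lines.append(seq)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
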