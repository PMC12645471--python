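"""Distance-based phylogenetics: alignment distances, neighbor joining, bootstrap.

Candidate halogenases recovered by motif mining are placed relative to
characterised FDHs with a neighbor-joining (NJ) tree built from global
pairwise alignment distances, with split support estimated by column
bootstrap.  NJ is exact on additive distance matrices, which is what the
synthetic generators exploit for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .motifs import ProteinSequence

__all__ = [
    "DistanceMatrix",
    "PhyloTree",
    "pairwise_distance",
    "neighbor_joining",
    "bootstrap_support",
    "alignment_distance_matrix",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """A symmetric, zero-diagonal matrix of pairwise distances over taxa."""

    taxa: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if d.shape != (n, n):
            raise ValueError(f"matrix shape {d.shape} does not match {n} taxa")
        if not np.all(np.isfinite(d)):
            raise ValueError("distance matrix contains non-finite entries")
        if np.any(d < 0):
            raise ValueError("distance matrix contains negative entries")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        object.__setattr__(self, "d", d)

    def __len__(self) -> int:
        return len(self.taxa)


@dataclass
class PhyloTree:
    """An unrooted tree with branch lengths and optional edge supports.

    Nodes are integers; leaves carry taxon names in ``leaf_names``.
    ``edges`` maps a frozenset pair {u, v} to its branch length;
    ``supports`` maps internal edges to bootstrap percentages in [0, 100].
    """

    leaf_names: dict[int, str]
    edges: dict[frozenset[int], float]
    supports: dict[frozenset[int], float] = field(default_factory=dict)

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(self.leaf_names.values())

    def _adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {}
        for e in self.edges:
            u, v = sorted(e)
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)
        return adj

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each as the smaller-or-canonical leaf set.

        Each internal edge induces a split of the taxa; trivial splits
        (single leaf vs rest) are omitted.
        """
        adj = self._adjacency()
        all_taxa = self.taxa
        out: set[frozenset[str]] = set()
        for e in self.edges:
            u, v = sorted(e)
            # collect leaves on the u side after cutting the edge
            seen = {u, v}
            stack = [u]
            side: set[str] = set()
            while stack:
                node = stack.pop()
                if node in self.leaf_names:
                    side.add(self.leaf_names[node])
                for nb in adj.get(node, []):
                    if nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            if 1 < len(side) < len(all_taxa) - 1:
                other = all_taxa - side
                out.add(min(frozenset(side), frozenset(other),
                            key=lambda s: (len(s), sorted(s))))
        return out

    def robinson_foulds(self, other: "PhyloTree") -> int:
        """Symmetric-difference (RF) distance between the two trees' splits."""
        if self.taxa != other.taxa:
            raise ValueError("trees are over different taxon sets")
        return len(self.splits() ^ other.splits())

    def path_lengths(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length (additive) distances."""
        adj = self._adjacency()
        names = sorted(self.leaf_names.values())
        idx = {n: i for i, n in enumerate(names)}
        n = len(names)
        d = np.zeros((n, n))
        for leaf, name in self.leaf_names.items():
            # Dijkstra is overkill: tree paths are unique; BFS with weights
            dist = {leaf: 0.0}
            stack = [leaf]
            while stack:
                node = stack.pop()
                for nb in adj.get(node, []):
                    if nb not in dist:
                        dist[nb] = dist[node] + self.edges[frozenset((node, nb))]
                        stack.append(nb)
            for other_leaf, other_name in self.leaf_names.items():
                d[idx[name], idx[other_name]] = dist[other_leaf]
        d = (d + d.T) / 2.0  # exact symmetry despite summation order
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix(taxa=tuple(names), d=d)

    def to_newick(self) -> str:
        """Newick string with branch lengths; supports (if any) as integer
        internal-node labels.  ASCII only."""
        adj = self._adjacency()
        # root at an internal node if possible (degree >= 2), else a leaf
        internal = [n for n in adj if n not in self.leaf_names]
        root = min(internal) if internal else min(adj)

        def render(node: int, parent: int | None) -> str:
            children = [nb for nb in adj[node] if nb != parent]
            if not children:  # leaf
                return self.leaf_names[node]
            inner = ",".join(
                render(c, node)
                + f":{self.edges[frozenset((node, c))]:.10g}"
                for c in children
            )
            label = ""
            if parent is not None:
                sup = self.supports.get(frozenset((node, parent)))
                if sup is not None:
                    label = str(int(round(sup)))
            return f"({inner}){label}"

        return render(root, None) + ";"


# ---------------------------------------------------------------------------
# distances


def _make_aligner(
    substitution_scores: str | tuple[float, float] = "blosum62",
    gap_penalty: float = 8.0,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if isinstance(substitution_scores, str):
        aligner.substitution_matrix = substitution_matrices.load(
            substitution_scores.upper()
        )
    else:
        match, mismatch = substitution_scores
        aligner.match_score = match
        aligner.mismatch_score = mismatch
    # linear gap cost: open == extend
    aligner.open_gap_score = -abs(gap_penalty)
    aligner.extend_gap_score = -abs(gap_penalty)
    return aligner


def _alignment_identity_fraction(alignment) -> float:
    """Identical aligned positions / aligned columns (gaps count in the
    denominator)."""
    a, b = alignment[0], alignment[1]
    ncols = len(a)
    ident = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return ident / ncols


def pairwise_distance(
    seqs: list[ProteinSequence],
    substitution_scores: str | tuple[float, float] = "blosum62",
    gap_penalty: float = 8.0,
) -> DistanceMatrix:
    """Global-alignment distances, d = 1 − fractional identity.

    Each pair is globally aligned by dynamic programming (linear gap
    cost); the distance is 1 minus the fraction of identically aligned
    columns, gap columns counting in the denominator.  The first
    co-optimal alignment is used, which makes the result deterministic.
    """
    if len(seqs) < 2:
        raise ValueError("at least two sequences are required")
    for s in seqs:
        if len(s) == 0:
            raise ValueError(f"sequence {s.id!r} has length 0")
    aligner = _make_aligner(substitution_scores, gap_penalty)
    n = len(seqs)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        aln = aligner.align(seqs[i].residues, seqs[j].residues)[0]
        dist = 1.0 - _alignment_identity_fraction(aln)
        d[i, j] = d[j, i] = dist
    return DistanceMatrix(taxa=tuple(s.id for s in seqs), d=d)


def alignment_distance_matrix(aligned: list[ProteinSequence]) -> DistanceMatrix:
    """Distances from an existing alignment: 1 − identity over all columns."""
    L = len(aligned[0].residues)
    if any(len(s.residues) != L for s in aligned):
        raise ValueError("aligned sequences have unequal lengths")
    n = len(aligned)
    arr = np.array([list(s.residues) for s in aligned])
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        ident = np.sum((arr[i] == arr[j]) & (arr[i] != "-"))
        d[i, j] = d[j, i] = 1.0 - ident / L
    return DistanceMatrix(taxa=tuple(s.id for s in aligned), d=d)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    Ties in the Q-matrix are broken by the lowest (i, j) index pair in
    the current working order; negative inferred branch lengths are
    clamped to zero.  For two taxa the single edge is split evenly.
    """
    n = len(D)
    if n < 2:
        raise ValueError("need at least two taxa")
    leaf_names = {i: t for i, t in enumerate(D.taxa)}
    edges: dict[frozenset[int], float] = {}
    if n == 2:
        # a midpoint node keeps the leaf/internal distinction uniform
        half = max(D.d[0, 1], 0.0) / 2.0
        edges[frozenset((0, 2))] = half
        edges[frozenset((1, 2))] = half
        return PhyloTree(leaf_names=leaf_names, edges=edges)

    active = list(range(n))          # node ids currently joinable
    dist = {(i, j): D.d[i, j] for i in range(n) for j in range(n)}
    next_id = n

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist[(i, k)] for k in active if k != i) for i in active}
        best = None
        best_q = np.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist[(i, j)] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best  # type: ignore[misc]
        dij = dist[(i, j)]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        u = next_id
        next_id += 1
        edges[frozenset((i, u))] = max(li, 0.0)
        edges[frozenset((j, u))] = max(lj, 0.0)
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (dist[(i, k)] + dist[(j, k)] - dij)
            dist[(u, k)] = dist[(k, u)] = duk
        dist[(u, u)] = 0.0
        active = [k for k in active if k not in (i, j)] + [u]

    # final three nodes join at one internal vertex
    a, b, c = active
    u = next_id
    la = 0.5 * (dist[(a, b)] + dist[(a, c)] - dist[(b, c)])
    lb = 0.5 * (dist[(a, b)] + dist[(b, c)] - dist[(a, c)])
    lc = 0.5 * (dist[(a, c)] + dist[(b, c)] - dist[(a, b)])
    edges[frozenset((a, u))] = max(la, 0.0)
    edges[frozenset((b, u))] = max(lb, 0.0)
    edges[frozenset((c, u))] = max(lc, 0.0)
    return PhyloTree(leaf_names=leaf_names, edges=edges)


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(
    aligned_seqs: list[ProteinSequence],
    n_replicates: int = 100,
    seed: int = 0,
) -> PhyloTree:
    """NJ tree from an alignment with column-bootstrap split supports.

    Columns are resampled with replacement per replicate (replicate ``r``
    uses seed ``seed + r``, giving reproducible parallel-safe streams);
    support for each internal split of the full-data tree is the
    percentage of replicate trees containing it.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    L = len(aligned_seqs[0].residues)
    if any(len(s.residues) != L for s in aligned_seqs):
        raise ValueError("aligned sequences have unequal lengths")

    full = neighbor_joining(alignment_distance_matrix(aligned_seqs))
    target_splits = full.splits()
    counts = {s: 0 for s in target_splits}

    arr = np.array([list(s.residues) for s in aligned_seqs])
    ids = [s.id for s in aligned_seqs]
    for r in range(n_replicates):
        rng = np.random.default_rng(seed + r)
        cols = rng.integers(0, L, size=L)
        resampled = [
            ProteinSequence(id=ids[k], residues="".join(arr[k, cols]))
            for k in range(len(ids))
        ]
        rep_tree = neighbor_joining(alignment_distance_matrix(resampled))
        for s in rep_tree.splits():
            if s in counts:
                counts[s] += 1

    # map split supports back onto internal edges of the full tree
    adj = full._adjacency()
    all_taxa = full.taxa
    for e in full.edges:
        u, v = sorted(e)
        seen = {u, v}
        stack = [u]
        side: set[str] = set()
        while stack:
            node = stack.pop()
            if node in full.leaf_names:
                side.add(full.leaf_names[node])
            for nb in adj.get(node, []):
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if 1 < len(side) < len(all_taxa) - 1:
            key = min(frozenset(side), frozenset(all_taxa - side),
                      key=lambda s: (len(s), sorted(s)))
            full.supports[e] = 100.0 * counts[key] / n_replicates
    return full
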