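"""Alignment distances, neighbor joining, and bootstrap supports."""

import numpy as np
import pytest

from haloscope.motifs import ProteinSequence
from haloscope.phylo import (
    DistanceMatrix,
    alignment_distance_matrix,
    bootstrap_support,
    neighbor_joining,
    pairwise_distance,
)
from haloscope.synthetic import gen_distances_from_tree, random_binary_tree


def brute_force_global_score(a, b, match, mismatch, gap):
    """Exhaustive best global-alignment score (linear gap cost)."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(i, j):
        if i == len(a) and j == len(b):
            return 0.0
        opts = []
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            opts.append(s + best(i + 1, j + 1))
        if i < len(a):
            opts.append(-gap + best(i + 1, j))
        if j < len(b):
            opts.append(-gap + best(i, j + 1))
        return max(opts)

    return best(0, 0)


def test_identical_sequences_have_zero_distance():
    seqs = [ProteinSequence("a", "MKLVW"), ProteinSequence("b", "MKLVW")]
    D = pairwise_distance(seqs)
    assert D.d[0, 1] == pytest.approx(0.0)


def test_distance_matrix_symmetric_zero_diagonal():
    rng = np.random.default_rng(0)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    seqs = [
        ProteinSequence(f"s{i}", "".join(rng.choice(aa, size=30)))
        for i in range(4)
    ]
    D = pairwise_distance(seqs)
    assert np.allclose(D.d, D.d.T)
    assert np.allclose(np.diag(D.d), 0)


def test_alignment_score_matches_brute_force_oracle():
    """DP global alignment equals exhaustive enumeration on short pairs."""
    from Bio import Align

    rng = np.random.default_rng(5)
    aa = list("ACDG")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = aligner.extend_gap_score = -2.0
    for _ in range(25):
        a = "".join(rng.choice(aa, size=rng.integers(1, 7)))
        b = "".join(rng.choice(aa, size=rng.integers(1, 7)))
        expected = brute_force_global_score(a, b, 2.0, -1.0, 2.0)
        assert aligner.score(a, b) == pytest.approx(expected)


def test_pairwise_distance_invariant_under_reordering():
    rng = np.random.default_rng(1)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    seqs = [
        ProteinSequence(f"s{i}", "".join(rng.choice(aa, size=25)))
        for i in range(4)
    ]
    D1 = pairwise_distance(seqs)
    perm = [2, 0, 3, 1]
    D2 = pairwise_distance([seqs[i] for i in perm])
    for ii, i in enumerate(perm):
        for jj, j in enumerate(perm):
            assert D2.d[ii, jj] == pytest.approx(D1.d[i, j], abs=1e-12)


def test_distance_matrix_validation():
    with pytest.raises(ValueError):
        DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError):
        DistanceMatrix(("a", "b"), np.array([[0.0, -1.0], [-1.0, 0.0]]))


def test_nj_three_taxon_closed_form():
    d_ab, d_ac, d_bc = 0.3, 0.5, 0.6
    D = DistanceMatrix(
        ("A", "B", "C"),
        np.array([[0, d_ab, d_ac], [d_ab, 0, d_bc], [d_ac, d_bc, 0]]),
    )
    tree = neighbor_joining(D)
    lengths = {
        tree.leaf_names[min(e)]: L for e, L in tree.edges.items()
    }
    assert lengths["A"] == pytest.approx((d_ab + d_ac - d_bc) / 2)
    assert lengths["B"] == pytest.approx((d_ab + d_bc - d_ac) / 2)
    assert lengths["C"] == pytest.approx((d_ac + d_bc - d_ab) / 2)


def test_nj_two_taxa_even_split():
    D = DistanceMatrix(("A", "B"), np.array([[0.0, 1.0], [1.0, 0.0]]))
    tree = neighbor_joining(D)
    assert sorted(tree.edges.values()) == [0.5, 0.5]


def test_nj_recovers_additive_five_taxon_tree():
    tree = random_binary_tree(5, seed=11)
    D, _ = gen_distances_from_tree(tree, seed=11)
    rec = neighbor_joining(D)
    assert rec.robinson_foulds(tree) == 0
    assert np.max(np.abs(rec.path_lengths().d - tree.path_lengths().d)) < 1e-9


def test_nj_agrees_with_skbio_topology():
    """Independent cross-check against scikit-bio's NJ on a noisy matrix."""
    skbio = pytest.importorskip("skbio")
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj as sk_nj

    tree = random_binary_tree(7, seed=3)
    D, _ = gen_distances_from_tree(tree, seed=3, noise=0.01)
    ours = neighbor_joining(D)
    sk_tree = sk_nj(SkDM(D.d, ids=list(D.taxa)))
    sk_splits = set()
    taxa = frozenset(D.taxa)
    for node in sk_tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            sk_splits.add(
                min(side, taxa - side, key=lambda s: (len(s), sorted(s)))
            )
    assert ours.splits() == sk_splits


def test_nj_rejects_bad_matrix():
    with pytest.raises(ValueError):
        neighbor_joining(
            DistanceMatrix(("a",), np.zeros((1, 1)))
        )


def test_newick_roundtrips_through_dendropy():
    dendropy = pytest.importorskip("dendropy")
    tree = random_binary_tree(6, seed=2)
    D, _ = gen_distances_from_tree(tree, seed=2)
    nwk = neighbor_joining(D).to_newick()
    parsed = dendropy.Tree.get(data=nwk, schema="newick")
    assert {t.taxon.label for t in parsed.leaf_node_iter()} == set(
        tree.leaf_names.values()
    )


def _clade_alignment(seed=0, L=150, n_mut=8):
    rng = np.random.default_rng(seed)
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    out = []
    for clade, base in (("a", rng.choice(aa, L)), ("b", rng.choice(aa, L))):
        for i in range(3):
            s = base.copy()
            idx = rng.choice(L, n_mut, replace=False)
            s[idx] = rng.choice(aa, n_mut)
            out.append(ProteinSequence(f"{clade}{i}", "".join(s)))
    return out


def test_bootstrap_supports_in_range_and_deterministic():
    seqs = _clade_alignment()
    t1 = bootstrap_support(seqs, n_replicates=30, seed=9)
    t2 = bootstrap_support(seqs, n_replicates=30, seed=9)
    assert t1.supports == t2.supports
    assert all(0 <= v <= 100 for v in t1.supports.values())


def test_bootstrap_supports_deep_clade_split():
    """Two deeply separated clades get near-unanimous support."""
    seqs = _clade_alignment()
    tree = bootstrap_support(seqs, n_replicates=100, seed=4)
    clade = frozenset({"a0", "a1", "a2"})
    supports = {}
    taxa = frozenset(tree.taxa)
    adj = tree._adjacency()
    for e, sup in tree.supports.items():
        u, v = sorted(e)
        seen = {u, v}
        stack = [u]
        side = set()
        while stack:
            n = stack.pop()
            if n in tree.leaf_names:
                side.add(tree.leaf_names[n])
            stack.extend(nb for nb in adj[n] if nb not in seen and not seen.add(nb))
        key = min(frozenset(side), taxa - frozenset(side),
                  key=lambda s: (len(s), sorted(s)))
        supports[key] = sup
    assert supports[clade] >= 95


def test_bootstrap_rejects_ragged_alignment():
    seqs = [ProteinSequence("a", "MKL"), ProteinSequence("b", "MK")]
    with pytest.raises(ValueError):
        bootstrap_support(seqs, n_replicates=5, seed=0)
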