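"""Nei DA distances, UPGMA clustering and Newick serialisation."""

import itertools
import math

import dendropy
import numpy as np
import pytest
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

from diallelkit import (
    DistanceMatrix,
    nei_da_distance,
    nei_standard_distance,
    pairwise_distances,
    simulate_parents,
    SimulationConfig,
    to_newick,
    upgma,
)

from conftest import make_table, random_table


def _weights(calls):
    return [None if c is None else {c: 1.0} for c in calls]


# ---------------------------------------------------------------------------
# Nei DA distance
# ---------------------------------------------------------------------------

def test_identical_homozygous_lines_have_zero_distance():
    w = _weights(["a"] * 11)
    assert nei_da_distance(w, w) == 0.0


def test_fully_mismatched_lines_have_distance_one():
    x = _weights([f"a{j}" for j in range(11)])
    y = _weights([f"b{j}" for j in range(11)])
    assert nei_da_distance(x, y) == 1.0


def test_partial_mismatch_equals_mismatch_proportion():
    x = _weights(["a"] * 11)
    y = _weights(["b"] * 4 + ["a"] * 7)
    assert nei_da_distance(x, y) == pytest.approx(4 / 11)


def test_no_shared_locus_is_an_error():
    with pytest.raises(ValueError, match="shared"):
        nei_da_distance(_weights([None, "a"]), _weights(["b", None]))


def test_missing_loci_excluded_pairwise():
    x = _weights(["a", None, "a", "a"])
    y = _weights(["b", "b", "a", None])
    # shared non-missing loci: 1 and 3 -> one mismatch of two
    assert nei_da_distance(x, y) == pytest.approx(0.5)


def test_heterozygote_dosages_enter_the_bhattacharyya_sum():
    x = [{"a": 0.5, "b": 0.5}]
    y = [{"a": 1.0}]
    assert nei_da_distance(x, y) == pytest.approx(1 - math.sqrt(0.5))


def test_nei_standard_distance_limits():
    same = _weights(["a", "b"])
    assert nei_standard_distance(same, same) == pytest.approx(0.0)
    disjoint = _weights(["a", "a"])
    other = _weights(["b", "b"])
    assert nei_standard_distance(disjoint, other) == math.inf


def test_nei_da_matches_brute_force_mismatch_on_random_tables(rng):
    """On homozygous lines DA is exactly the per-pair mismatch proportion."""
    for _ in range(60):
        table = random_table(rng, n_lines=4, n_loci=6, n_alleles=3,
                             missing_rate=0.15)
        try:
            dm = pairwise_distances(table)
        except ValueError:
            continue  # a pair with no shared scored locus
        for a, b in itertools.combinations(table.line_ids, 2):
            shared = [
                (table.calls.at[a, l], table.calls.at[b, l])
                for l in table.loci
                if table.calls.at[a, l] is not None
                and table.calls.at[b, l] is not None
            ]
            expected = sum(x != y for x, y in shared) / len(shared)
            assert dm.get(a, b) == pytest.approx(expected, abs=1e-12)


def test_distance_is_pseudometric_on_random_tables(rng):
    for _ in range(30):
        table = random_table(rng, n_lines=5, n_loci=7, n_alleles=3)
        d = pairwise_distances(table).values
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert ((d >= 0) & (d <= 1)).all()
        for i, j, k in itertools.permutations(range(5), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


def test_distance_invariant_to_locus_and_line_order(rng):
    table = random_table(rng, n_lines=5, n_loci=8, n_alleles=4)
    dm = pairwise_distances(table)
    shuffled = make_table(
        {line: [table.calls.at[line, l] for l in reversed(table.loci)]
         for line in reversed(table.line_ids)},
        loci=list(reversed(table.loci)),
    )
    dm2 = pairwise_distances(shuffled)
    for a, b in itertools.combinations(table.line_ids, 2):
        assert dm.get(a, b) == pytest.approx(dm2.get(a, b), abs=1e-15)


def test_simulated_parents_give_valid_full_matrix():
    table = simulate_parents(SimulationConfig(seed=11))
    dm = pairwise_distances(table)
    assert dm.values.shape == (8, 8)
    iu = np.triu_indices(8, k=1)
    assert len(dm.values[iu]) == 28


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def naive_upgma_heights(labels, matrix):
    """O(n^3) reference: cluster distance recomputed as the mean over all
    member pairs of the ORIGINAL matrix at every step."""
    clusters = [frozenset([i]) for i in range(len(labels))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([matrix[i, j] for i in clusters[a]
                             for j in clusters[b]])
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        d, a, b = best
        merged = clusters[a] | clusters[b]
        merges.append((frozenset(clusters[a]), frozenset(clusters[b]), d / 2))
        clusters = ([c for k, c in enumerate(clusters) if k not in (a, b)])
        clusters.append(merged)
        clusters.sort(key=min)
    return merges


def _tree_merges(node, labels_to_index):
    """(left leafset, right leafset, height) triples of an internal node."""
    out = []
    if node.is_leaf:
        return out
    left, right = node.children
    out += _tree_merges(left, labels_to_index) + _tree_merges(right, labels_to_index)
    ls = frozenset(labels_to_index[x] for x in left.leaves())
    rs = frozenset(labels_to_index[x] for x in right.leaves())
    out.append((ls, rs, node.height))
    return out


def test_upgma_hand_agglomeration_three_taxa():
    dm = DistanceMatrix(("A", "B", "C"),
                        np.array([[0, .2, .6], [.2, 0, .6], [.6, .6, 0]]))
    tree = upgma(dm)
    assert tree.height == pytest.approx(0.3)
    inner = [c for c in tree.children if not c.is_leaf][0]
    assert inner.height == pytest.approx(0.1)
    assert sorted(inner.leaves()) == ["A", "B"]
    assert to_newick(tree) == "((A:0.1,B:0.1):0.2,C:0.3);"


def test_upgma_two_leaves():
    dm = DistanceMatrix(("A", "B"), np.array([[0, .4], [.4, 0]]))
    tree = upgma(dm)
    assert tree.height == pytest.approx(0.2)
    assert sorted(tree.leaves()) == ["A", "B"]


def test_upgma_rejects_invalid_matrices():
    with pytest.raises(ValueError):
        DistanceMatrix(("A", "B"), np.array([[0, .4], [.5, 0]]))
    with pytest.raises(ValueError):
        DistanceMatrix(("A", "B"), np.array([[0, -.1], [-.1, 0]]))


def test_upgma_matches_naive_reimplementation_small_matrices(rng):
    for n in (2, 3, 4, 5, 6):
        for _ in range(25):
            m = rng.random((n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            labels = tuple(chr(65 + i) for i in range(n))
            tree = upgma(DistanceMatrix(labels, m))
            idx = {lab: i for i, lab in enumerate(labels)}
            got = {(min(l, r, key=min), max(l, r, key=min)): h
                   for l, r, h in _tree_merges(tree, idx)}
            expected = {(min(l, r, key=min), max(l, r, key=min)): h
                        for l, r, h in naive_upgma_heights(labels, m)}
            assert got.keys() == expected.keys()
            for key in expected:
                assert got[key] == pytest.approx(expected[key], abs=1e-10)


def test_upgma_heights_match_scipy_average_linkage(rng):
    for n in (4, 6, 8):
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        labels = tuple(f"T{i}" for i in range(n))
        tree = upgma(DistanceMatrix(labels, m))
        idx = {lab: i for i, lab in enumerate(labels)}
        ours = sorted(h for _, _, h in _tree_merges(tree, idx))
        scipy_heights = sorted(average(squareform(m))[:, 2] / 2)
        assert np.allclose(ours, scipy_heights, atol=1e-10)


def test_upgma_merge_heights_monotone_and_leaves_conserved(rng):
    table = random_table(rng, n_lines=7, n_loci=9, n_alleles=3)
    dm = pairwise_distances(table)
    tree = upgma(dm)
    assert sorted(tree.leaves()) == sorted(table.line_ids)

    def check(node, parent_h):
        assert node.height <= parent_h + 1e-12
        if not node.is_leaf:
            for c in node.children:
                check(c, node.height)

    check(tree, math.inf)


def test_upgma_exact_on_ultrametric_input():
    # cophenetic distances of a known ultrametric tree
    labels = ("A", "B", "C", "D")
    m = np.array([
        [0.0, 0.2, 0.8, 0.8],
        [0.2, 0.0, 0.8, 0.8],
        [0.8, 0.8, 0.0, 0.4],
        [0.8, 0.8, 0.4, 0.0],
    ])
    tree = upgma(DistanceMatrix(labels, m))
    coph = tree.cophenetic()
    for i, j in itertools.combinations(range(4), 2):
        assert coph[frozenset((labels[i], labels[j]))] == pytest.approx(m[i, j])


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def test_single_leaf_newick_flag():
    from diallelkit.distance import DendrogramNode
    leaf = DendrogramNode(0.0, label="A")
    assert to_newick(leaf) == "A:0.0;"
    assert to_newick(leaf, leaf_lengths=False) == "A;"


def test_newick_roundtrip_preserves_topology_and_heights(rng):
    table = random_table(rng, n_lines=6, n_loci=10, n_alleles=4)
    dm = pairwise_distances(table)
    tree = upgma(dm)
    parsed = dendropy.Tree.get(data=to_newick(tree), schema="newick")
    parsed_pdm = parsed.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in parsed.taxon_namespace}
    coph = tree.cophenetic()
    for pair, expected in coph.items():
        a, b = sorted(pair)
        got = parsed_pdm.patristic_distance(taxa[a], taxa[b])
        assert got == pytest.approx(expected, abs=1e-6)
    assert to_newick(tree).endswith(";")
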