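"""Pairwise genetic distances among inbred lines and UPGMA dendrograms.

The default distance is Nei's DA over multi-allelic loci,

    DA = 1 - (1/L) * sum_loci sum_alleles sqrt(x_a * y_a),

with x_a, y_a the within-line allele dosages.  For fully homozygous lines the
inner sum is 1 where the two lines carry the same allele and 0 otherwise, so
DA reduces to the proportion of compared loci at which the allele labels
differ.  Loci with a missing call in either line are excluded pairwise (the
denominator L is per-pair).  Nei's standard distance D = -ln(I) is available
as an option.

Clustering is classic UPGMA: agglomerate the closest pair, with the distance
between clusters equal to the arithmetic mean of all member-pair distances
(size-weighted Lance-Williams update); node height is half the merge
distance, giving an ultrametric tree serialisable as Newick.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .markers import GenotypeTable

__all__ = [
    "DistanceMatrix",
    "DendrogramNode",
    "nei_da_distance",
    "nei_standard_distance",
    "pairwise_distances",
    "upgma",
    "to_newick",
    "write_distance_matrix",
]

AlleleWeights = Mapping[str, float]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric labelled distance matrix with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")
        if (v < -1e-12).any():
            raise ValueError("negative distances")
        object.__setattr__(self, "values", v)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels),
                            columns=list(self.labels))


@dataclass(frozen=True)
class DendrogramNode:
    """Node of an ultrametric dendrogram.

    Leaves have ``height`` 0 and a ``label``; internal nodes have exactly two
    ``children`` and ``height`` equal to half the merge distance.
    """

    height: float
    label: str | None = None
    children: tuple["DendrogramNode", "DendrogramNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        left, right = self.children  # type: ignore[misc]
        return left.leaves() + right.leaves()

    def cophenetic(self) -> dict[frozenset[str], float]:
        """Cophenetic distance (2 * height of the LCA) for every leaf pair."""
        out: dict[frozenset[str], float] = {}
        if self.is_leaf:
            return out
        left, right = self.children  # type: ignore[misc]
        out.update(left.cophenetic())
        out.update(right.cophenetic())
        for a in left.leaves():
            for b in right.leaves():
                out[frozenset((a, b))] = 2.0 * self.height
        return out


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def nei_da_distance(
    x: Sequence[AlleleWeights | None],
    y: Sequence[AlleleWeights | None],
) -> float:
    """Nei DA distance between two lines given per-locus allele weights.

    ``x`` and ``y`` are parallel sequences over the shared loci; entries are
    allele->dosage mappings or None for a missing call.  Loci missing in
    either line are dropped; at least one shared locus is required.
    """
    if len(x) != len(y):
        raise ValueError("lines scored at different numbers of loci")
    total, used = 0.0, 0
    for wx, wy in zip(x, y):
        if wx is None or wy is None:
            continue
        used += 1
        total += sum(math.sqrt(wx[a] * wy[a]) for a in wx.keys() & wy.keys())
    if used == 0:
        raise ValueError("no shared non-missing locus between the two lines")
    return 1.0 - total / used


def nei_standard_distance(
    x: Sequence[AlleleWeights | None],
    y: Sequence[AlleleWeights | None],
) -> float:
    """Nei's standard genetic distance D = -ln(I).

    I = Jxy / sqrt(Jx * Jy) with J terms averaged over shared loci.  Identical
    lines give 0; lines with no allele in common give +inf.
    """
    if len(x) != len(y):
        raise ValueError("lines scored at different numbers of loci")
    jx = jy = jxy = 0.0
    used = 0
    for wx, wy in zip(x, y):
        if wx is None or wy is None:
            continue
        used += 1
        jx += sum(p * p for p in wx.values())
        jy += sum(p * p for p in wy.values())
        jxy += sum(wx[a] * wy[a] for a in wx.keys() & wy.keys())
    if used == 0:
        raise ValueError("no shared non-missing locus between the two lines")
    if jxy == 0.0:
        return math.inf
    identity = jxy / math.sqrt(jx * jy)
    return -math.log(min(identity, 1.0))


_METHODS = {"nei-da": nei_da_distance, "nei-standard": nei_standard_distance}


def pairwise_distances(table: GenotypeTable,
                       method: str = "nei-da") -> DistanceMatrix:
    """All-pairs distance matrix among the lines of a genotype table."""
    if method not in _METHODS:
        raise ValueError(f"unknown distance method {method!r}")
    if len(table.line_ids) < 2:
        raise ValueError("need at least 2 lines")
    dist = _METHODS[method]
    lines = table.line_ids
    weights = {
        line: [table.allele_weights(line, locus) for locus in table.loci]
        for line in lines
    }
    n = len(lines)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = dist(weights[lines[i]], weights[lines[j]])
    return DistanceMatrix(tuple(lines), d)


def write_distance_matrix(dm: DistanceMatrix, path: str | Path,
                          sep: str = "\t") -> None:
    dm.to_dataframe().to_csv(path, sep=sep, index_label="line")


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def upgma(dm: DistanceMatrix) -> DendrogramNode:
    """UPGMA agglomeration of a distance matrix into an ultrametric tree.

    At each step the closest pair of clusters merges at height d/2; the
    distance from the merged cluster to any other is the size-weighted mean
    of the two members' distances (equivalent to averaging all member-pair
    distances of the original matrix).  Ties in the closest-pair search break
    on the lowest (row, column) position so trees are deterministic.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least 2 labels to cluster")
    d = dm.values.astype(float).copy()
    nodes: list[DendrogramNode] = [DendrogramNode(0.0, label=lab)
                                   for lab in dm.labels]
    sizes = [1] * n
    active = list(range(n))

    while len(active) > 1:
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                if best is None or d[i, j] < best[0] - 1e-15:
                    best = (d[i, j], i, j)
        dist, i, j = best  # type: ignore[misc]
        merged = DendrogramNode(dist / 2.0, children=(nodes[i], nodes[j]))
        # size-weighted average update; store the merged cluster in slot i
        for k in active:
            if k in (i, j):
                continue
            d[i, k] = d[k, i] = (
                sizes[i] * d[i, k] + sizes[j] * d[j, k]
            ) / (sizes[i] + sizes[j])
        nodes[i] = merged
        sizes[i] += sizes[j]
        active.remove(j)
    root = nodes[active[0]]
    _check_monotone(root)
    return root


def _check_monotone(node: DendrogramNode, parent_height: float = math.inf) -> None:
    if node.height > parent_height + 1e-9:
        raise AssertionError("non-monotone merge heights")
    if not node.is_leaf:
        for child in node.children:  # type: ignore[union-attr]
            _check_monotone(child, node.height)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def to_newick(tree: DendrogramNode, leaf_lengths: bool = True,
              precision: int = 6) -> str:
    """Serialise a dendrogram as Newick with branch lengths.

    Branch length of a node is parent height minus child height; with
    ``leaf_lengths=False`` a single-leaf tree renders as ``"A;"``.
    """

    def fmt(x: float) -> str:
        return f"{x:.{precision}g}"

    def render(node: DendrogramNode, parent_height: float) -> str:
        length = parent_height - node.height
        if node.is_leaf:
            return f"{node.label}:{fmt(length)}"
        left, right = node.children  # type: ignore[misc]
        inner = f"({render(left, node.height)},{render(right, node.height)})"
        return f"{inner}:{fmt(length)}"

    if tree.is_leaf:
        return f"{tree.label}:0.0;" if leaf_lengths else f"{tree.label};"
    left, right = tree.children  # type: ignore[misc]
    return f"({render(left, tree.height)},{render(right, tree.height)});"
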