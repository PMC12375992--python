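"""Structure-based distance matrices, UPGMA trees, and clade assignment.

An all-vs-all comparison of Calpha models yields a symmetric distance
matrix d = 1 - TM (TM averaged over both normalisation directions, so the
distance is symmetric and length-aware). Average-linkage (UPGMA)
agglomeration produces an ultrametric tree whose horizontal cut at the
height giving exactly k subtrees defines the clade assignment — mirroring
how a structure dendrogram of hydrophobin models is read off into a small
number of main clades (six in the full-corpus analysis).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .structcompare import tm_score
from .structio import StructureModel


@dataclass(frozen=True)
class StructureDistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(v, v.T) or np.any(np.diag(v) != 0) or np.any(v < 0):
            raise ValueError("distance matrix must be symmetric, non-negative, zero-diagonal")


@dataclass(frozen=True)
class CladeTree:
    """Ultrametric tree from UPGMA: linkage matrix, labels, Newick text."""

    labels: tuple[str, ...]  # lexicographically sorted leaf order
    linkage: np.ndarray  # scipy linkage matrix (merge distances)
    newick: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def merge_heights(self) -> np.ndarray:
        """Node heights (half the merge distance), non-decreasing."""
        return self.linkage[:, 2] / 2.0


def structure_distance_matrix(
    models: Mapping[str, StructureModel] | Sequence[tuple[str, StructureModel]],
) -> StructureDistanceMatrix:
    """Pairwise 1 - TM distances over a set of labelled models.

    TM is computed in both normalisation directions and averaged, making
    the matrix exactly symmetric.
    """
    items = list(models.items()) if isinstance(models, Mapping) else list(models)
    if len(items) < 2:
        raise ValueError("at least 2 models required")
    labels = tuple(lbl for lbl, _ in items)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate structure labels")
    n = len(items)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            la, ma = items[i]
            lb, mb = items[j]
            try:
                t_ab = tm_score(ma, mb).score
                t_ba = tm_score(mb, ma).score
            except ValueError as exc:
                raise ValueError(f"pair ({la}, {lb}): {exc}") from exc
            mat[i, j] = mat[j, i] = 1.0 - 0.5 * (t_ab + t_ba)
    return StructureDistanceMatrix(labels=labels, values=np.clip(mat, 0.0, 1.0))


def _newick(node: hierarchy.ClusterNode, labels: Sequence[str]) -> str:
    """Serialise with branch lengths = parent height - own height.

    Children are ordered by their lexicographically smallest leaf so the
    text form is canonical.
    """

    def min_leaf(n: hierarchy.ClusterNode) -> str:
        if n.is_leaf():
            return labels[n.id]
        return min(min_leaf(n.left), min_leaf(n.right))

    def children(n: hierarchy.ClusterNode) -> list[hierarchy.ClusterNode]:
        return sorted((n.left, n.right), key=min_leaf)

    def rec(n: hierarchy.ClusterNode, parent_height: float) -> str:
        h = n.dist / 2.0
        if n.is_leaf():
            return f"{labels[n.id]}:{parent_height:g}"
        inner = "(" + ",".join(rec(c, h) for c in children(n)) + ")"
        return inner if parent_height == h else f"{inner}:{parent_height - h:g}"

    if node.is_leaf():
        return labels[node.id] + ";"
    root_h = node.dist / 2.0
    return "(" + ",".join(rec(c, root_h) for c in children(node)) + ");"


def upgma_tree(matrix: StructureDistanceMatrix) -> CladeTree:
    """Average-linkage agglomeration of a structure distance matrix.

    Labels are sorted lexicographically before clustering so that tied
    merges resolve identically regardless of input order; node heights are
    half the merge distance (ultrametric).
    """
    order = np.argsort(np.asarray(matrix.labels))
    labels = tuple(matrix.labels[i] for i in order)
    values = matrix.values[np.ix_(order, order)]
    z = hierarchy.linkage(squareform(values, checks=False), method="average")
    root = hierarchy.to_tree(z)
    return CladeTree(labels=labels, linkage=z, newick=_newick(root, labels))


def assign_clades(tree: CladeTree, k: int) -> dict[str, int]:
    """Cut the ultrametric tree into exactly k clades.

    Applies the first (n - k) merges of the agglomeration, i.e. cuts just
    below the (n - k + 1)-th merge height (ties resolve to the lower
    height). Clade indices (1-based) are ordered by each clade's
    lexicographically first leaf label.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m in range(n - k):
        a, b = int(tree.linkage[m, 0]), int(tree.linkage[m, 1])
        node = n + m
        parent[find(a)] = node
        parent[find(b)] = node

    roots: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for leaf, label in enumerate(tree.labels):  # labels already sorted
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots) + 1
        assignment[label] = roots[r]
    return assignment


def clade_table(assignment: Mapping[str, int]) -> pd.DataFrame:
    """TSV-ready clade assignment (label, clade index)."""
    return pd.DataFrame(
        sorted(assignment.items()), columns=["label", "clade"]
    )


#: a qualitative palette for iTOL-style annotation of up to 12 clades
_PALETTE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd", "#8c564b",
    "#e377c2", "#7f7f7f", "#bcbd22", "#17becf", "#aec7e8", "#ffbb78",
)


def itol_annotation(assignment: Mapping[str, int]) -> pd.DataFrame:
    """Leaf-colour annotation table (label, clade, colour hex)."""
    rows = [
        {"label": lbl, "clade": c, "color": _PALETTE[(c - 1) % len(_PALETTE)]}
        for lbl, c in sorted(assignment.items())
    ]
    return pd.DataFrame(rows)
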