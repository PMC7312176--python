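"""Euclidean distance matrices over PCNVs and neighbor-joining trees.

The distance between two sequences is the unweighted Euclidean distance
between their 18-dimensional vectors.  Trees are built with the canonical
Saitou–Nei neighbor-joining algorithm: at each step join the pair (i, j)
minimising

    Q(i, j) = (r - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)

where r is the number of active nodes, then attach i and j to a new node
with the standard branch-length formulas and reduce the matrix.  Ties in Q
are broken by the lowest (i, j) index pair in current matrix order, so the
result is deterministic.  Negative branch lengths (which NJ can produce on
non-additive input) are clamped to zero by default; the pre-clamp values
are recorded on the tree for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import PCNVector

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "euclidean_distance_matrix",
    "nj_tree",
    "to_newick",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """A labeled symmetric nonnegative matrix of pairwise distances."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=np.float64)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if d.shape != (n, n):
            raise ValueError(f"matrix shape {d.shape} does not match {n} labels")
        if not np.array_equal(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(d < 0):
            raise ValueError("distance matrix entries must be nonnegative")
        object.__setattr__(self, "d", d)

    def __len__(self) -> int:
        return len(self.labels)

    def permuted(self, order: Sequence[int]) -> "DistanceMatrix":
        idx = np.asarray(order)
        return DistanceMatrix(
            tuple(self.labels[i] for i in idx), self.d[np.ix_(idx, idx)]
        )


@dataclass
class TreeNode:
    """A node of an (unrooted, stored rooted-at-top) phylogenetic tree."""

    name: str | None = None
    length: float = 0.0  # branch length to parent; meaningless at the top node
    children: list["TreeNode"] = field(default_factory=list)
    pre_clamp_length: float | None = None  # original value when clamped

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]


@dataclass
class PhyloTree:
    """An unrooted tree over taxa, stored with an arbitrary top-level
    multifurcation (the final NJ join), serializable to Newick."""

    root: TreeNode

    def leaf_names(self) -> set[str]:
        return {lf.name for lf in self.root.leaves()}

    def newick(self) -> str:
        return to_newick(self)

    def leaf_distances(self) -> dict[frozenset, float]:
        """Path lengths between every pair of leaves (for testing and
        diagnostics)."""
        # accumulate distances from each node down to its leaves
        def walk(node: TreeNode) -> list[tuple[str, float]]:
            if node.is_leaf:
                return [(node.name, node.length)]
            below = []
            per_child = []
            for c in node.children:
                sub = walk(c)
                per_child.append(sub)
                below.extend(sub)
            for i in range(len(per_child)):
                for j in range(i + 1, len(per_child)):
                    for na, da in per_child[i]:
                        for nb, db in per_child[j]:
                            out[frozenset((na, nb))] = da + db
            return [(n, d + node.length) for n, d in below]

        out: dict[frozenset, float] = {}
        walk(self.root)
        return out


def euclidean_distance_matrix(vectors: Sequence[PCNVector]) -> DistanceMatrix:
    """Pairwise Euclidean distances between 18-dimensional vectors.

    No component scaling or weighting is applied: counts, means, variances
    and covariances enter on their natural scales.
    """
    if len(vectors) < 2:
        raise ValueError("need at least 2 vectors")
    ids = [v.source_id for v in vectors]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate vector source ids")
    X = np.vstack([v.as_array() for v in vectors])
    d = squareform(pdist(X, metric="euclidean"))
    return DistanceMatrix(tuple(ids), d)


def _quote_label(name: str) -> str:
    if any(c in name for c in " \t()[]':;,"):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(tree: PhyloTree) -> str:
    """Serialize with branch lengths; labels quoted when needed."""

    def fmt(node: TreeNode, top: bool) -> str:
        if node.is_leaf:
            body = _quote_label(node.name or "")
        else:
            body = "(" + ",".join(fmt(c, False) for c in node.children) + ")"
        return body if top else f"{body}:{node.length:.10g}"

    return fmt(tree.root, True) + ";"


def nj_tree(matrix: DistanceMatrix, allow_negative: bool = False) -> PhyloTree:
    """Saitou–Nei neighbor joining on a distance matrix of >= 3 taxa.

    Deterministic: Q-ties are broken by the lowest (i, j) pair in current
    matrix order.  Branch lengths are clamped at zero unless
    ``allow_negative`` is set; clamped nodes keep their pre-clamp value in
    ``pre_clamp_length``.
    """
    n = len(matrix)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")

    d = matrix.d.copy()
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in matrix.labels]

    def set_length(node: TreeNode, length: float) -> None:
        if length < 0 and not allow_negative:
            node.pre_clamp_length = length
            node.length = 0.0
        else:
            node.length = float(length)

    while len(nodes) > 3:
        r = len(nodes)
        row_sums = d.sum(axis=1)
        q = (r - 2) * d - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (i, j) among minima, scanning i then j, i < j
        iu = np.triu_indices(r, k=1)
        flat = q[iu]
        k = int(np.argmin(flat))  # argmin returns the first minimum: tie rule
        i, j = int(iu[0][k]), int(iu[1][k])

        li = 0.5 * d[i, j] + (row_sums[i] - row_sums[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        parent = TreeNode(children=[nodes[i], nodes[j]])
        set_length(nodes[i], li)
        set_length(nodes[j], lj)

        # distances from the new node to every remaining node
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(r) if x not in (i, j)]
        new_d = np.zeros((r - 1, r - 1))
        new_d[: r - 2, : r - 2] = d[np.ix_(keep, keep)]
        new_d[: r - 2, r - 2] = new_d[r - 2, : r - 2] = dk[keep]
        d = new_d
        nodes = [nodes[x] for x in keep] + [parent]

    # closing three-taxon join: star with exact branch lengths
    a, b, c = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    top = TreeNode(children=[a, b, c])
    set_length(a, la)
    set_length(b, lb)
    set_length(c, lc)
    return PhyloTree(root=top)
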