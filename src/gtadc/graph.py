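"""Spot graph from a random projection forest.

Each tree recursively splits the points by projecting onto a random unit
direction and cutting at the median projection; points sharing a leaf are
connected with weight 1. Averaging the 0/1 adjacency over T trees yields a
weighted graph whose edge weights are leaf co-occurrence frequencies in
[0, 1] — a robust locality measure that, unlike a plain k-NN graph, adapts
neighborhood size to the local geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import scipy.io
import scipy.sparse as sp


@dataclass
class RPNode:
    """Internal node (direction + offset, two children) or leaf (indices)."""

    indices: Optional[np.ndarray] = None
    direction: Optional[np.ndarray] = None
    offset: float = 0.0
    left: Optional["RPNode"] = None
    right: Optional["RPNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.indices is not None


@dataclass
class RPTree:
    root: RPNode
    n: int
    leaf_size: int

    def leaves(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node.indices)
            else:
                stack.extend((node.left, node.right))
        return out


@dataclass
class WeightedAdjacency:
    """Symmetric n × n tree-co-occurrence weights on the 1/T grid, zero diagonal."""

    A: sp.csr_matrix
    n_trees: int

    def __post_init__(self) -> None:
        self.A = sp.csr_matrix(self.A)
        if self.A.shape[0] != self.A.shape[1]:
            raise ValueError("adjacency must be square")

    @property
    def n(self) -> int:
        return self.A.shape[0]

    def toarray(self) -> np.ndarray:
        return self.A.toarray()

    def export(self, path: str | Path) -> None:
        scipy.io.mmwrite(Path(path), sp.coo_matrix(self.A))


def _build(indices: np.ndarray, X: np.ndarray, leaf_size: int, rng: np.random.Generator) -> RPNode:
    if indices.size <= leaf_size:
        return RPNode(indices=indices)
    for _ in range(3):  # retry degenerate directions (all projections equal)
        direction = rng.standard_normal(X.shape[1])
        norm = np.linalg.norm(direction)
        if norm == 0:
            continue
        direction /= norm
        proj = X[indices] @ direction
        offset = float(np.median(proj))
        left = indices[proj <= offset]   # ties go to the lower half
        right = indices[proj > offset]
        if left.size and right.size:
            node = RPNode(direction=direction, offset=offset)
            node.left = _build(left, X, leaf_size, rng)
            node.right = _build(right, X, leaf_size, rng)
            return node
    # all points project identically (e.g. duplicates): keep as one leaf
    return RPNode(indices=indices)


def build_tree(X: np.ndarray, leaf_size: int = 40, rng: np.random.Generator | int | None = None) -> RPTree:
    """Recursive median-split random projection tree over the rows of X."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("X must be a nonempty 2-D point matrix")
    if leaf_size < 2:
        raise ValueError("leaf_size must be >= 2")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    root = _build(np.arange(X.shape[0]), X, leaf_size, rng)
    return RPTree(root=root, n=X.shape[0], leaf_size=leaf_size)


def tree_adjacency(tree: RPTree, n: int | None = None) -> sp.csr_matrix:
    """0/1 adjacency: (i, j) = 1 iff i ≠ j share a leaf."""
    n = tree.n if n is None else n
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    for leaf in tree.leaves():
        if leaf.size < 2:
            continue
        r, c = np.meshgrid(leaf, leaf, indexing="ij")
        mask = r != c
        rows.append(r[mask])
        cols.append(c[mask])
    if not rows:
        return sp.csr_matrix((n, n))
    data = np.ones(sum(r.size for r in rows))
    return sp.csr_matrix(
        (data, (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )


def forest_adjacency(
    X: np.ndarray, T: int = 10, leaf_size: int = 40, seed: int = 0
) -> WeightedAdjacency:
    """Average the adjacency of T independent random projection trees."""
    if T < 1:
        raise ValueError("T must be >= 1")
    X = np.asarray(X, dtype=float)
    streams = np.random.SeedSequence(seed).spawn(T)
    acc: sp.csr_matrix | None = None
    for t in range(T):
        tree = build_tree(X, leaf_size=leaf_size, rng=np.random.default_rng(streams[t]))
        At = tree_adjacency(tree)
        acc = At if acc is None else acc + At
    A = acc.multiply(1.0 / T).tocsr()
    return WeightedAdjacency(A=A, n_trees=T)
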