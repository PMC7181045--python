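"""Agglomerative Ward clustering of the unlabeled pool.

A binary merge tree over the pool samples is built bottom-up: at every step
the pair of clusters whose union least increases the total error sum of
squares (ESS) about cluster centroids is merged — the Ward criterion.  The
tree is what the active sampler prunes: an antichain of nodes covering all
leaves is a *pruning*, and cutting away the highest merges yields the
initial working pruning.

Costs are maintained incrementally through the Lance-Williams form of the
Ward increase,  delta(c1, c2) = n1 n2 / (n1 + n2) * ||o1 - o2||^2,  which is
validated in tests against direct recomputation of the merged-cluster ESS.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


def euclidean(x1: np.ndarray, x2: np.ndarray) -> float:
    """Plain Euclidean distance between two points."""
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    if x1.shape != x2.shape:
        raise ValueError("points must have equal dimension")
    return float(np.sqrt(np.sum((x1 - x2) ** 2)))


def ess(points: np.ndarray) -> float:
    """Error sum of squares of a point set about its centroid."""
    points = np.atleast_2d(points)
    centroid = points.mean(axis=0)
    return float(np.sum((points - centroid) ** 2))


def ward_cost(c1: np.ndarray, c2: np.ndarray) -> float:
    """ESS of the merged cluster about its centroid (the Ward similarity)."""
    c1 = np.atleast_2d(c1)
    c2 = np.atleast_2d(c2)
    if c1.shape[0] == 0 or c2.shape[0] == 0:
        raise ValueError("clusters must be non-empty")
    return ess(np.vstack([c1, c2]))


def ward_increase(c1: np.ndarray, c2: np.ndarray) -> float:
    """Increase in total ESS caused by merging the two clusters."""
    return ward_cost(c1, c2) - ess(np.atleast_2d(c1)) - ess(np.atleast_2d(c2))


@dataclass
class Node:
    """Tree node; leaves carry a sample id, internal nodes a merge height."""

    index: int
    left: "Node | None" = None
    right: "Node | None" = None
    height: float = 0.0
    sample_id: int | None = None
    leaf_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def n_leaves(self) -> int:
        return self.leaf_ids.shape[0]


@dataclass
class HCTree:
    """Binary Ward merge tree; nodes[0..n_u-1] are leaves in input order,
    internal nodes follow in merge order (so the root is nodes[-1])."""

    nodes: list[Node]
    n_leaves: int

    @property
    def root(self) -> Node:
        return self.nodes[-1]

    @property
    def merge_order(self) -> list[Node]:
        return self.nodes[self.n_leaves:]

    def to_json(self) -> str:
        def encode(node: Node):
            if node.is_leaf:
                return {"node": node.index, "sample_id": int(node.sample_id)}
            return {
                "node": node.index,
                "height": node.height,
                "children": [encode(node.left), encode(node.right)],
                "leaf_ids": node.leaf_ids.tolist(),
            }

        return json.dumps(encode(self.root))


def build_tree(X_pool: np.ndarray, ids: np.ndarray | None = None) -> HCTree:
    """Greedy Ward agglomeration of the pool samples.

    At each step the pair of active clusters with the smallest ESS increase
    is merged; ties break toward the lexicographically smallest pair of
    minimum member ids, which makes the tree invariant to row permutation.
    Merged centroids are accumulated with the smaller-min-id cluster first so
    the arithmetic itself is permutation-stable.
    """
    X = np.atleast_2d(np.asarray(X_pool, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points to build a tree")
    if ids is None:
        ids = np.arange(n, dtype=np.int64)
    ids = np.asarray(ids, dtype=np.int64)

    nodes = [
        Node(index=i, sample_id=int(ids[i]), leaf_ids=np.array([ids[i]], dtype=np.int64))
        for i in range(n)
    ]
    # slot s holds one live cluster; merging frees the partner's slot
    centroid = X.astype(float).copy()
    size = np.ones(n)
    min_id = ids.astype(np.int64).copy()
    slot_node = np.arange(n)                 # node index per live slot
    alive = np.ones(n, dtype=bool)

    def costs_against(s: int) -> np.ndarray:
        """Ward increase of slot s against every live slot (inf elsewhere)."""
        d = centroid - centroid[s]
        sq = np.einsum("ij,ij->i", d, d)
        c = size * size[s] / (size + size[s]) * sq
        c[~alive] = np.inf
        c[s] = np.inf
        return c

    C = np.full((n, n), np.inf)
    for s in range(n):
        C[s] = costs_against(s)

    for step in range(n - 1):
        cmin = C.min()
        # tie-break among exact-minimum pairs by (min id, max id)
        rows, cols = np.nonzero(C == cmin)
        best = None
        for r, c_ in zip(rows, cols):
            if r > c_:
                continue
            key = (min(min_id[r], min_id[c_]), max(min_id[r], min_id[c_]))
            if best is None or key < best[0]:
                best = (key, r, c_)
        _, a, b = best
        # accumulate with the smaller-min-id cluster first (stable arithmetic)
        if min_id[b] < min_id[a]:
            a, b = b, a
        new_index = n + step
        node = Node(
            index=new_index,
            left=nodes[slot_node[a]],
            right=nodes[slot_node[b]],
            height=float(cmin),
            leaf_ids=np.sort(
                np.concatenate(
                    [nodes[slot_node[a]].leaf_ids, nodes[slot_node[b]].leaf_ids]
                )
            ),
        )
        nodes.append(node)
        centroid[a] = (size[a] * centroid[a] + size[b] * centroid[b]) / (
            size[a] + size[b]
        )
        size[a] = size[a] + size[b]
        min_id[a] = min(min_id[a], min_id[b])
        slot_node[a] = new_index
        alive[b] = False
        C[b, :] = np.inf
        C[:, b] = np.inf
        fresh = costs_against(a)
        C[a, :] = fresh
        C[:, a] = fresh
    return HCTree(nodes=nodes, n_leaves=n)


def initial_pruning(tree: HCTree, max_nodes: int) -> list[Node]:
    """Cut the tree by undoing its ``max_nodes - 1`` final merges.

    Ward merge heights are non-decreasing along the merge sequence
    (reducibility), so the last merges are the largest-height ones; undoing
    them leaves a forest whose roots form an antichain of exactly
    ``max_nodes`` nodes covering every leaf once.
    """
    n_u = tree.n_leaves
    if not 1 <= max_nodes <= n_u:
        raise ValueError(f"max_nodes={max_nodes} outside [1, {n_u}]")
    removed = {nd.index for nd in tree.merge_order[len(tree.merge_order) - (max_nodes - 1):]}
    pruning: list[Node] = []

    def collect(node: Node) -> None:
        if node.index in removed:
            collect(node.left)
            collect(node.right)
        else:
            pruning.append(node)

    collect(tree.root)
    return pruning


def check_antichain(tree: HCTree, pruning: list[Node]) -> bool:
    """True iff the node set covers every leaf exactly once."""
    covered = np.concatenate([nd.leaf_ids for nd in pruning])
    return (
        covered.shape[0] == tree.n_leaves
        and np.array_equal(np.sort(covered), np.sort(tree.root.leaf_ids))
    )
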