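"""Bottom-up hierarchical clustering from a distance matrix.

The agglomerative loop is implemented literally: every round, linkage
distances between all pairs of live clusters are recomputed from the full
distance matrix and the closest pair is merged.  No Lance–Williams update
shortcuts are used — O(n^3) is ample for the few hundred items this
package targets, and the literal form matches the single/average/complete
linkage definitions exactly.  Ties are broken by the lexicographically
smallest pair of cluster representative labels (the minimum leaf label in
each cluster), which makes the output invariant to input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .distances import DistanceMatrix

__all__ = [
    "Dendrogram",
    "LINKAGES",
    "cluster_linkage_distance",
    "agglomerative_cluster",
    "dendrogram_to_newick",
]

LINKAGES = ("single", "average", "complete")


@dataclass
class Dendrogram:
    """Rooted binary merge tree over labeled leaves.

    Nodes are integer ids: leaves are ``0..N-1`` (indexing ``leaves``),
    internal nodes ``N..2N-2`` in creation order, the root is ``2N-2``.
    ``merges[i]`` holds the two child ids of internal node ``N+i`` and
    ``heights[i]`` its merge height.
    """

    leaves: list[str]
    merges: np.ndarray  # (N-1, 2) int
    heights: np.ndarray  # (N-1,) float

    def __post_init__(self) -> None:
        n = len(self.leaves)
        self.merges = np.asarray(self.merges, dtype=np.int64).reshape(n - 1, 2)
        self.heights = np.asarray(self.heights, dtype=np.float64).reshape(n - 1)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def root(self) -> int:
        return 2 * self.n_leaves - 2

    def children(self, node: int) -> tuple[int, int]:
        if node < self.n_leaves:
            raise ValueError(f"node {node} is a leaf")
        left, right = self.merges[node - self.n_leaves]
        return int(left), int(right)

    def node_height(self, node: int) -> float:
        if node < self.n_leaves:
            return 0.0
        return float(self.heights[node - self.n_leaves])

    def leaf_sets(self) -> list[frozenset[int]]:
        """Leaf-index set below every node, indexed by node id."""
        n = self.n_leaves
        sets: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
        for left, right in self.merges:
            sets.append(sets[left] | sets[right])
        return sets

    def node_labels(self, node: int) -> frozenset[str]:
        return frozenset(self.leaves[i] for i in self.leaf_sets()[node])


def cluster_linkage_distance(
    P: Iterable[str],
    Q: Iterable[str],
    matrix: DistanceMatrix,
    linkage: str,
) -> float:
    """Distance between two disjoint clusters of labeled items.

    single = min, average = mean, complete = max over the |P|·|Q| cross
    pairs.
    """
    P, Q = set(P), set(Q)
    if not P or not Q:
        raise ValueError("clusters must be non-empty")
    if P & Q:
        raise ValueError(f"clusters overlap on {sorted(P & Q)}")
    idx = {label: i for i, label in enumerate(matrix.item_ids)}
    rows = [idx[p] for p in P]
    cols = [idx[q] for q in Q]
    cross = matrix.values[np.ix_(rows, cols)]
    if linkage == "single":
        return float(cross.min())
    if linkage == "average":
        return float(cross.mean())
    if linkage == "complete":
        return float(cross.max())
    raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")


def agglomerative_cluster(matrix: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    """Merge the closest pair of clusters until one cluster remains.

    The recorded merge height is the linkage distance of the merged pair.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    n = len(matrix.item_ids)
    if n < 2:
        raise ValueError("need at least two items")

    # clusters: node id -> (leaf index set, representative label)
    active: dict[int, tuple[frozenset[int], str]] = {
        i: (frozenset([i]), matrix.item_ids[i]) for i in range(n)
    }
    merges = np.zeros((n - 1, 2), dtype=np.int64)
    heights = np.zeros(n - 1)
    d = matrix.values

    def link(a: frozenset[int], b: frozenset[int]) -> float:
        cross = d[np.ix_(sorted(a), sorted(b))]
        return {"single": cross.min, "average": cross.mean, "complete": cross.max}[
            linkage
        ]()

    for step in range(n - 1):
        best = None
        ids = sorted(active)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                u, v = ids[ai], ids[bi]
                dist = link(active[u][0], active[v][0])
                ra, rb = sorted((active[u][1], active[v][1]))
                key = (dist, ra, rb)
                if best is None or key < best[0]:
                    best = (key, u, v)
        (dist, ra, _), u, v = best
        merges[step] = (u, v)
        heights[step] = dist
        new_id = n + step
        active[new_id] = (active[u][0] | active[v][0], ra)
        del active[u], active[v]

    return Dendrogram(list(matrix.item_ids), merges, heights)


def _quote_label(label: str) -> str:
    if any(ch in label for ch in " \t()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def dendrogram_to_newick(tree: Dendrogram) -> str:
    """Serialize a dendrogram as a rooted Newick string.

    Branch lengths are merge-height differences between a node and its
    parent (leaves sit at height 0), so root-to-leaf path lengths equal
    the root merge height.
    """
    def render(node: int, parent_height: float) -> str:
        length = parent_height - tree.node_height(node)
        if node < tree.n_leaves:
            return f"{_quote_label(tree.leaves[node])}:{length!r}"
        left, right = tree.children(node)
        h = tree.node_height(node)
        return f"({render(left, h)},{render(right, h)}):{length!r}"

    root = tree.root
    h = tree.node_height(root)
    left, right = tree.children(root)
    return f"({render(left, h)},{render(right, h)});"
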