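"""Rand-optimal conversion of a dendrogram into a flat clustering.

Given a reference classification of the leaves, the dendrogram is cut
into a tree-consistent partition (every cluster is the full leaf set of
one node) that maximizes the Rand index against the reference.  The
optimum is found by an exact dynamic program over the binary tree: a
node's leaf set becomes one cluster whenever doing so scores at least as
well as the best partitions of its two subtrees combined.  Two
consequences follow directly: same-class sibling leaves always share a
cluster label, and a leaf whose sibling belongs to another class can be
split off into its own cluster.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Iterator, Mapping

import numpy as np

from .agglomerative import Dendrogram

__all__ = [
    "ReferenceClassification",
    "FlatClustering",
    "subtree_gain",
    "optimal_flat_clustering",
    "enumerate_tree_partitions",
]

_MAX_ENUM_LEAVES = 16


@dataclass(frozen=True)
class ReferenceClassification:
    """Known class (clade) label for every item."""

    classes: Mapping[str, str]

    @property
    def class_sizes(self) -> Counter:
        return Counter(self.classes.values())

    @property
    def n_classes(self) -> int:
        return len(set(self.classes.values()))

    def different_class_pairs(self) -> int:
        """Number of unordered item pairs whose classes differ."""
        n = len(self.classes)
        same = sum(comb(s, 2) for s in self.class_sizes.values())
        return comb(n, 2) - same


@dataclass(frozen=True)
class FlatClustering:
    """Partition of items into clusters with dense integer ids."""

    assignments: Mapping[str, int]

    def clusters(self) -> dict[int, frozenset[str]]:
        out: dict[int, set[str]] = {}
        for item, cid in self.assignments.items():
            out.setdefault(cid, set()).add(item)
        return {cid: frozenset(members) for cid, members in out.items()}


def subtree_gain(class_counts: Mapping[str, int] | Iterable[int]) -> int:
    """Pair score of making one cluster out of M leaves with the given
    per-class counts: (same-class pairs) − (different-class pairs)
    = ``2·sum_c C(m_c, 2) − C(M, 2)``.

    This is the node's contribution to TP + TN relative to splitting all
    its leaves apart, so the tree DP maximizes exactly the Rand numerator.
    """
    counts = list(class_counts.values()) if isinstance(class_counts, Mapping) else list(class_counts)
    M = sum(counts)
    if M < 1:
        raise ValueError("empty subtree")
    same = sum(comb(m, 2) for m in counts)
    return 2 * same - comb(M, 2)


def _dp_scores(tree: Dendrogram, ref: ReferenceClassification):
    """Per-node class counts, gains and DP scores (vectorized)."""
    n = tree.n_leaves
    class_labels = sorted(set(ref.classes.values()))
    class_idx = {c: i for i, c in enumerate(class_labels)}
    t = len(class_labels)

    missing = [lab for lab in tree.leaves if lab not in ref.classes]
    if missing:
        raise KeyError(f"leaves missing from reference classification: {missing}")

    counts = np.zeros((2 * n - 1, t), dtype=np.int64)
    for i, lab in enumerate(tree.leaves):
        counts[i, class_idx[ref.classes[lab]]] = 1
    for step, (left, right) in enumerate(tree.merges):
        counts[n + step] = counts[left] + counts[right]

    M = counts.sum(axis=1)
    same = (counts * (counts - 1) // 2).sum(axis=1)
    gain = 2 * same - M * (M - 1) // 2

    score = np.zeros(2 * n - 1, dtype=np.int64)
    for step in range(n - 1):
        left, right = tree.merges[step]
        child_sum = score[left] + score[right]
        score[n + step] = max(gain[n + step], child_sum)
    return gain, score


def optimal_flat_clustering(tree: Dendrogram, ref: ReferenceClassification) -> FlatClustering:
    """Tree-consistent partition of the leaves maximizing the Rand index.

    The DP keeps, for every node, the best achievable pair score over
    partitions of its subtree; a node is collapsed into a single cluster
    iff its own gain is at least the children's combined best (merging
    preferred on ties, so fewer clusters win when scores are equal).
    Cluster ids are assigned in pre-order over the chosen nodes.
    """
    gain, score = _dp_scores(tree, ref)
    n = tree.n_leaves

    assignments: dict[str, int] = {}
    next_id = 0

    def assign(node: int) -> None:
        nonlocal next_id
        if node < n or gain[node] >= score[tree.children(node)[0]] + score[tree.children(node)[1]]:
            cid = next_id
            next_id += 1
            stack = [node]
            while stack:
                v = stack.pop()
                if v < n:
                    assignments[tree.leaves[v]] = cid
                else:
                    stack.extend(tree.children(v))
        else:
            left, right = tree.children(node)
            assign(left)
            assign(right)

    import sys
    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 4 * n + 100))
    try:
        assign(tree.root)
    finally:
        sys.setrecursionlimit(old_limit)
    return FlatClustering(assignments)


def max_tree_rand(tree: Dendrogram, ref: ReferenceClassification) -> float:
    """Best achievable Rand for the given tree, from the DP root score.

    Equals ``(score(root) + D) / C(N, 2)`` with D the number of
    different-class pairs in the reference.
    """
    _, score = _dp_scores(tree, ref)
    N = tree.n_leaves
    return (int(score[tree.root]) + ref.different_class_pairs()) / comb(N, 2)


def enumerate_tree_partitions(tree: Dendrogram) -> Iterator[frozenset[frozenset[str]]]:
    """Yield every tree-consistent partition of the leaves (test oracle).

    A partition is an antichain of nodes whose leaf sets cover all
    leaves.  Guarded to ≤ 16 leaves (the count grows roughly like the
    number of subtrees of the tree).
    """
    if tree.n_leaves > _MAX_ENUM_LEAVES:
        raise ValueError(f"enumeration guarded to {_MAX_ENUM_LEAVES} leaves")

    n = tree.n_leaves

    def parts(node: int) -> list[tuple[frozenset[str], ...]]:
        own = (tree.node_labels(node),)
        if node < n:
            return [own]
        left, right = tree.children(node)
        out = [own]
        for lp in parts(left):
            for rp in parts(right):
                out.append(lp + rp)
        return out

    for p in parts(tree.root):
        yield frozenset(p)
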