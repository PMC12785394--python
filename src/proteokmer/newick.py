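"""Newick import for dendrograms, backed by dendropy.

Only strictly binary trees can be represented as a :class:`Dendrogram`;
merge heights are reconstructed as each node's maximum distance to a
descendant leaf, which inverts the branch lengths written by
:func:`proteokmer.agglomerative.dendrogram_to_newick` exactly for
ultrametric trees.
"""

from __future__ import annotations

import numpy as np

from .agglomerative import Dendrogram

__all__ = ["parse_newick"]


def parse_newick(text: str) -> Dendrogram:
    import dendropy

    tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)

    leaves: list[str] = []
    merges: list[tuple[int, int]] = []  # placeholder ids: leaves >= 0, internal < 0
    heights: list[float] = []

    def walk(node) -> tuple[int, float]:
        """Return (placeholder node id, height above deepest leaf)."""
        children = node.child_nodes()
        if not children:
            label = node.taxon.label if node.taxon else (node.label or "")
            leaves.append(label)
            return len(leaves) - 1, 0.0
        if len(children) != 2:
            raise ValueError("dendrogram import requires a strictly binary tree")
        (lid, lh), (rid, rh) = (walk(c) for c in children)
        height = max(lh + (children[0].edge.length or 0.0),
                     rh + (children[1].edge.length or 0.0))
        merges.append((lid, rid))
        heights.append(height)
        return -len(merges), height

    walk(tree.seed_node)
    n = len(leaves)
    merge_arr = np.array(
        [[c if c >= 0 else n + (-c - 1) for c in pair] for pair in merges],
        dtype=np.int64,
    )
    return Dendrogram(leaves, merge_arr, np.array(heights))
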