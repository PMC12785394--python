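"""Optional adapters for off-the-shelf non-hierarchical clusterers.

Thin pass-throughs to scikit-learn methods that accept a precomputed
distance matrix (Affinity Propagation, DBSCAN, OPTICS, HDBSCAN), for
side-by-side comparison with the package's own agglomerative pipeline.
These are conveniences around external implementations, not part of the
tested core; their hyperparameters are forwarded verbatim.
"""

from __future__ import annotations

from typing import Any

from .distances import DistanceMatrix
from .tree_flatten import FlatClustering

_METHODS = {
    "affinity_propagation": ("AffinityPropagation", {"affinity": "precomputed"}),
    "dbscan": ("DBSCAN", {"metric": "precomputed"}),
    "optics": ("OPTICS", {"metric": "precomputed"}),
    "hdbscan": ("HDBSCAN", {"metric": "precomputed"}),
}


def sklearn_cluster(matrix: DistanceMatrix, method: str, **params: Any) -> FlatClustering:
    """Cluster a distance matrix with a scikit-learn method.

    Affinity Propagation expects similarities; the negated distance
    matrix is passed in that case.  Noise points (label -1) each become
    their own singleton cluster so the result is a proper partition.
    """
    try:
        import sklearn.cluster as skc
    except ImportError as exc:  # pragma: no cover
        raise ImportError("scikit-learn is required for comparison clusterers") from exc
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_METHODS)}")
    cls_name, defaults = _METHODS[method]
    estimator = getattr(skc, cls_name)(**{**defaults, **params})
    X = -matrix.values if method == "affinity_propagation" else matrix.values
    labels = estimator.fit_predict(X)
    next_id = int(labels.max()) + 1
    assignments = {}
    for item, label in zip(matrix.item_ids, labels):
        if label < 0:
            label, next_id = next_id, next_id + 1
        assignments[item] = int(label)
    return FlatClustering(assignments)
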