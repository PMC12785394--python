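"""Distance functions between k-mer frequency vectors.

Four families are provided: the generalized Minkowski-style distance
``(sum |p_i - q_i|**b) ** (1/a)`` (L1 at a=b=1, L2 at a=b=2), the Pearson
correlation distance ``(1 - r) / 2``, and the top-k-mer intersection
distance ``1 - |P_a ∩ Q_a| / s`` comparing the sets of the ``s =
round(a*n)`` most frequent k-mer types of each vector.  The intersection
measure is stored as a dissimilarity (0 for identical top sets) so that
all four families plug into distance-based clustering uniformly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence, Union

import numpy as np

from .kmer_space import KmerSpec, KmerVector

__all__ = [
    "DistanceMatrix",
    "TopKmerSet",
    "minkowski_distance",
    "correlation_distance",
    "top_kmer_set",
    "intersection_distance",
    "get_metric",
    "distance_matrix",
    "METRIC_NAMES",
]

#: Metric selectors accepted throughout the package (the studied grid).
METRIC_NAMES = ("l1", "l2", "corr", "inter_0.1", "inter_0.05")


@dataclass(frozen=True)
class TopKmerSet:
    """The indices of the ``round(a*n)`` most frequent k-mer types of a vector."""

    spec: KmerSpec
    fraction: float
    members: frozenset[int]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with stable item labels."""

    item_ids: list[str]
    values: np.ndarray
    metric_tag: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.item_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match item count")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.item_ids.index(pair[0])
        j = self.item_ids.index(pair[1])
        return float(self.values[i, j])

    def to_json(self) -> str:
        return json.dumps(
            {"ids": self.item_ids, "metric": self.metric_tag,
             "matrix": self.values.tolist()},
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "DistanceMatrix":
        obj = json.loads(text)
        return cls(list(obj["ids"]), np.array(obj["matrix"]), obj["metric"])


def _check_pair(p: KmerVector, q: KmerVector) -> None:
    if p.values.shape != q.values.shape:
        raise ValueError(
            f"dimension mismatch: {p.values.shape} vs {q.values.shape}"
        )


def minkowski_distance(p: KmerVector, q: KmerVector, a: float = 1.0, b: float = 1.0) -> float:
    """Generalized distance ``(sum_i |p_i - q_i|**b) ** (1/a)``.

    ``a = b = 1`` is the Manhattan (L1) distance, ``a = b = 2`` the
    Euclidean (L2) distance.  Other (a, b) combinations are accepted but
    were not part of the studied metric grid.
    """
    _check_pair(p, q)
    if a <= 0 or b <= 0:
        raise ValueError("parameters a and b must be positive")
    return float(np.sum(np.abs(p.values - q.values) ** b) ** (1.0 / a))


def correlation_distance(p: KmerVector, q: KmerVector) -> float:
    """Pearson correlation distance ``(1 - r(p, q)) / 2`` in [0, 1]."""
    _check_pair(p, q)
    x, y = p.values, q.values
    if x.size < 2:
        raise ValueError("correlation needs dimension >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    vx = float(xc @ xc)
    vy = float(yc @ yc)
    if vx == 0.0 or vy == 0.0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(xc @ yc) / np.sqrt(vx * vy)
    return (1.0 - min(1.0, max(-1.0, r))) / 2.0


def top_kmer_set(v: KmerVector, a: float) -> TopKmerSet:
    """Indices of the ``s = round(a*n)`` highest-frequency k-mer types.

    Ties at the cutoff frequency are broken by ascending k-mer index, so
    the set is deterministic for any input.
    """
    if not (0.0 < a < 1.0):
        raise ValueError(f"fraction a must be in (0, 1), got {a}")
    n = v.spec.n
    s = int(np.floor(a * n + 0.5))  # round half up
    if s == 0:
        raise ValueError(f"a*n rounds to zero (a={a}, n={n})")
    # stable sort on (-freq, index): equal frequencies keep ascending index
    order = np.argsort(-v.values, kind="stable")
    return TopKmerSet(v.spec, a, frozenset(int(i) for i in order[:s]))


def intersection_distance(p: KmerVector, q: KmerVector, a: float) -> float:
    """``1 - |P_a ∩ Q_a| / s``: dissimilarity of the two top-k-mer sets."""
    _check_pair(p, q)
    ps = top_kmer_set(p, a)
    qs = top_kmer_set(q, a)
    s = len(ps.members)
    return 1.0 - len(ps.members & qs.members) / s


Metric = Callable[[KmerVector, KmerVector], float]


def get_metric(name: str) -> Metric:
    """Resolve a metric selector (``l1``, ``l2``, ``corr``, ``inter_<a>``)."""
    key = name.lower()
    if key == "l1":
        return lambda p, q: minkowski_distance(p, q, 1.0, 1.0)
    if key == "l2":
        return lambda p, q: minkowski_distance(p, q, 2.0, 2.0)
    if key == "corr":
        return correlation_distance
    if key.startswith("inter_"):
        a = float(key.split("_", 1)[1])
        return lambda p, q: intersection_distance(p, q, a)
    raise ValueError(f"unknown metric {name!r}")


def distance_matrix(
    vectors: Mapping[str, KmerVector],
    metric: Union[str, Metric],
    metric_tag: str | None = None,
) -> DistanceMatrix:
    """All-pairs distance matrix over labeled vectors.

    Labels keep their mapping order; the matrix itself does not depend on
    that order beyond row/column placement.
    """
    if len(vectors) < 2:
        raise ValueError("need at least two vectors")
    if isinstance(metric, str):
        metric_tag = metric_tag or metric
        metric = get_metric(metric)
    ids = list(vectors.keys())
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = metric(vectors[ids[i]], vectors[ids[j]])
            except ValueError as exc:
                raise ValueError(
                    f"metric failed on pair ({ids[i]!r}, {ids[j]!r}): {exc}"
                ) from exc
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids, values, metric_tag or getattr(metric, "__name__", "custom"))
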