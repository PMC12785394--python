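"""Clustering evaluation: Rand index and the random-tree null model.

The Rand index counts the fraction of item pairs placed consistently by
a clustering and a reference classification.  Because the tree-to-flat
conversion in this package is Rand-optimal for any tree, even random
trees score high; significance is therefore calibrated against the Rand
distribution of uniformly generated random binary trees, summarized by a
maximum-likelihood location-scale Student-t fit and a right-tail
critical value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .agglomerative import Dendrogram
from .tree_flatten import FlatClustering, ReferenceClassification, optimal_flat_clustering

__all__ = [
    "ContingencyCounts",
    "NullDistribution",
    "contingency_counts",
    "rand_index",
    "random_binary_tree",
    "null_rand_distribution",
    "significance_test",
    "critical_value_from_moments",
]


@dataclass(frozen=True)
class ContingencyCounts:
    """Pair counts between a clustering and a classification.

    TP: same cluster & same class; FP: same cluster, different class;
    FN: different cluster, same class; TN: different both.  They sum to
    C(N, 2).
    """

    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    @property
    def rand(self) -> float:
        return (self.TP + self.TN) / self.total


def contingency_counts(
    clustering: FlatClustering, ref: ReferenceClassification
) -> ContingencyCounts:
    items = sorted(clustering.assignments)
    if set(items) != set(ref.classes):
        raise ValueError("clustering and reference cover different item sets")
    N = len(items)
    cluster_ids = {c: i for i, c in enumerate(sorted(set(clustering.assignments.values())))}
    class_ids = {c: i for i, c in enumerate(sorted(set(ref.classes.values())))}
    table = np.zeros((len(cluster_ids), len(class_ids)), dtype=np.int64)
    for item in items:
        table[cluster_ids[clustering.assignments[item]], class_ids[ref.classes[item]]] += 1

    def pairs(x: np.ndarray) -> int:
        return int((x.astype(np.int64) * (x - 1) // 2).sum())

    total = comb(N, 2)
    tp = pairs(table)
    same_cluster = pairs(table.sum(axis=1))
    same_class = pairs(table.sum(axis=0))
    fp = same_cluster - tp
    fn = same_class - tp
    tn = total - tp - fp - fn
    return ContingencyCounts(tp, fp, fn, tn)


def rand_index(clustering: FlatClustering, ref: ReferenceClassification) -> float:
    """``(TP + TN) / C(N, 2)`` — 1 iff the partitions agree up to renaming."""
    return contingency_counts(clustering, ref).rand


def random_binary_tree(leaf_labels: Sequence[str], rng: np.random.Generator | int) -> Dendrogram:
    """Uniform random binary tree by sequential root joining.

    Starting from singleton roots, two live roots are chosen uniformly at
    random (without replacement) and joined; the merge height of the j-th
    join is j.  Deterministic given the generator state or seed.
    """
    n = len(leaf_labels)
    if n < 2:
        raise ValueError("need at least two leaves")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    roots = list(range(n))
    merges = np.zeros((n - 1, 2), dtype=np.int64)
    heights = np.arange(1, n, dtype=np.float64)
    for step in range(n - 1):
        i, j = rng.choice(len(roots), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        merges[step] = (roots[i], roots[j])
        roots[j] = n + step  # replace one, drop the other
        roots.pop(i)
    return Dendrogram(list(leaf_labels), merges, heights)


@dataclass
class NullDistribution:
    """Rand samples from random trees plus a fitted t null."""

    samples: np.ndarray
    n_trees: int
    fitted_df: float
    fitted_loc: float
    fitted_scale: float
    critical_value: float
    alpha: float
    seed: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.samples))

    @property
    def sd(self) -> float:
        return float(np.std(self.samples, ddof=1))

    def to_dict(self) -> dict:
        return {
            "n_trees": self.n_trees,
            "alpha": self.alpha,
            "seed": self.seed,
            "mean": self.mean,
            "sd": self.sd,
            "fitted_df": self.fitted_df,
            "fitted_loc": self.fitted_loc,
            "fitted_scale": self.fitted_scale,
            "critical_value": self.critical_value,
            "samples": self.samples.tolist(),
        }


def critical_value_from_moments(loc: float, sd: float, df: float, alpha: float = 0.05) -> float:
    """Right-tail critical value of a location-scale t given its mean and
    *standard deviation* (converted to the scale parameter via
    ``scale = sd / sqrt(df / (df - 2))``, valid for df > 2)."""
    if df <= 2:
        raise ValueError("standard deviation undefined for df <= 2")
    scale = sd / np.sqrt(df / (df - 2.0))
    return float(loc + scale * stats.t.ppf(1.0 - alpha, df))


def null_rand_distribution(
    ref: ReferenceClassification,
    n_trees: int = 10_000,
    alpha: float = 0.05,
    rng_seed: int = 0,
) -> NullDistribution:
    """Rand distribution of Rand-optimally flattened random trees.

    For each of `n_trees` uniform random binary trees over the reference
    items, the tree is flattened by the Rand-maximizing conversion and
    scored; the samples are then fitted with a maximum-likelihood
    location-scale Student t, and the critical value is
    ``loc + scale * t_{1-alpha}(df)``.
    """
    if n_trees < 100:
        raise ValueError("need at least 100 trees for a stable fit")
    labels = sorted(ref.classes)
    if len(labels) < 2:
        raise ValueError("reference must contain at least two items")
    rng = np.random.default_rng(rng_seed)
    samples = np.empty(n_trees)
    for i in range(n_trees):
        tree = random_binary_tree(labels, rng)
        samples[i] = rand_index(optimal_flat_clustering(tree, ref), ref)
    df, loc, scale = stats.t.fit(samples)
    critical = float(loc + scale * stats.t.ppf(1.0 - alpha, df))
    return NullDistribution(
        samples=samples,
        n_trees=n_trees,
        fitted_df=float(df),
        fitted_loc=float(loc),
        fitted_scale=float(scale),
        critical_value=critical,
        alpha=alpha,
        seed=rng_seed,
    )


def significance_test(observed_rand: float, null: NullDistribution) -> tuple[bool, float]:
    """Right-sided test against the fitted t null.

    Returns (significant, p-value): significant iff the observed Rand
    strictly exceeds the critical value; the p-value is the fitted-t
    upper tail at the observed value.
    """
    p = float(stats.t.sf(observed_rand, null.fitted_df, null.fitted_loc, null.fitted_scale))
    return observed_rand > null.critical_value, p


def empirical_tail_p(observed_rand: float, null: NullDistribution) -> float:
    """Fraction of null samples at or above the observed value (reported
    alongside the parametric p for transparency)."""
    return float(np.mean(null.samples >= observed_rand))
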