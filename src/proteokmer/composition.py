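"""Abundant-k-mer overlap and within/between-group distance analyses.

Two questions are addressed with the same machinery at either the
proteome level (groups = clades) or the protein level (groups =
functional labels such as membrane / ribosomal / nucleotide-binding):

* how much do the sets of most abundant k-mer types overlap across
  organisms (top ``I_t``% of types, shared by at least ``I_c``% of the
  vectors), and
* are groups separable by average pairwise distance — comparing the mean
  within-group distance ``D_i`` (over unordered distinct pairs) with the
  mean between-group distance ``D_ij`` (over all cross pairs), including
  a one-standard-deviation separation margin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .distances import Metric, get_metric, top_kmer_set
from .kmer_space import KmerVector

__all__ = [
    "AbundanceParams",
    "common_abundant_kmers",
    "within_group_distance",
    "between_group_distance",
    "group_separation_report",
]


@dataclass(frozen=True)
class AbundanceParams:
    """Top-fraction percentage ``I_t`` and commonality percentage ``I_c``."""

    top_percent: float = 10.0    # I_t
    common_percent: float = 90.0  # I_c

    def __post_init__(self) -> None:
        if not (0 < self.top_percent < 100):
            raise ValueError("top_percent must be in (0, 100)")
        if not (0 < self.common_percent <= 100):
            raise ValueError("common_percent must be in (0, 100]")


def common_abundant_kmers(
    vectors: Sequence[KmerVector], params: AbundanceParams
) -> frozenset[int]:
    """k-mer types in the top ``I_t``% of at least ``I_c``% of the vectors.

    Per vector the top ``round((I_t/100)·n)`` types are taken (same
    semantics and tie rule as the intersection distance); a type counts
    as common when it appears in at least ``ceil((I_c/100)·len(vectors))``
    of those top sets.
    """
    if not vectors:
        raise ValueError("need at least one vector")
    a = params.top_percent / 100.0
    threshold = math.ceil(params.common_percent / 100.0 * len(vectors))
    occurrence: dict[int, int] = {}
    for v in vectors:
        for idx in top_kmer_set(v, a).members:
            occurrence[idx] = occurrence.get(idx, 0) + 1
    return frozenset(idx for idx, c in occurrence.items() if c >= threshold)


def _resolve(metric: Union[str, Metric]) -> Metric:
    return get_metric(metric) if isinstance(metric, str) else metric


def within_group_distance(group: Sequence[KmerVector], metric: Union[str, Metric]) -> float:
    """Mean distance over all unordered distinct pairs of one group:
    ``D_i = 2·sum_{p<q} d(p,q) / (N_i (N_i - 1))``."""
    if len(group) < 2:
        raise ValueError("within-group distance needs at least two members")
    m = _resolve(metric)
    total = sum(m(p, q) for p, q in combinations(group, 2))
    n = len(group)
    return 2.0 * total / (n * (n - 1))


def between_group_distance(
    group_i: Sequence[KmerVector],
    group_j: Sequence[KmerVector],
    metric: Union[str, Metric],
) -> float:
    """Mean distance over all cross pairs:
    ``D_ij = sum_{p∈Q_i, q∈Q_j} d(p,q) / (N_i N_j)``."""
    if not group_i or not group_j:
        raise ValueError("both groups must be non-empty")
    m = _resolve(metric)
    total = sum(m(p, q) for p in group_i for q in group_j)
    return total / (len(group_i) * len(group_j))


def group_separation_report(
    grouped: Mapping[str, Sequence[KmerVector]],
    metric: Union[str, Metric],
) -> dict:
    """Within/between distance summary and the separation margin.

    Returns per-group ``D_i``, all pairwise ``D_ij``, their means and
    standard deviations (population SD over groups / group pairs), and
    the margin ``(m2 - s2) - (m1 + s1)``: positive when between-group
    distances exceed within-group distances even after moving one SD
    toward each other, i.e. when the grouping is separable.
    """
    if len(grouped) < 2:
        raise ValueError("need at least two groups")
    names = sorted(grouped)
    within = {g: within_group_distance(grouped[g], metric) for g in names}
    between = {
        (gi, gj): between_group_distance(grouped[gi], grouped[gj], metric)
        for gi, gj in combinations(names, 2)
    }
    w = np.array(list(within.values()))
    b = np.array(list(between.values()))
    m1, s1 = float(w.mean()), float(w.std())
    m2, s2 = float(b.mean()), float(b.std())
    margin = (m2 - s2) - (m1 + s1)
    return {
        "within": within,
        "between": {f"{gi}|{gj}": v for (gi, gj), v in between.items()},
        "within_mean": m1,
        "within_sd": s1,
        "between_mean": m2,
        "between_sd": s2,
        "margin": margin,
        "separable": bool(margin > 0),
        "degenerate": bool(m1 == 0 and m2 == 0),
    }


def separation_table(report: dict) -> pd.DataFrame:
    """Between-group distance matrix as a DataFrame (within on the diagonal)."""
    names = sorted(report["within"])
    df = pd.DataFrame(index=names, columns=names, dtype=float)
    for g, v in report["within"].items():
        df.loc[g, g] = v
    for key, v in report["between"].items():
        gi, gj = key.split("|")
        df.loc[gi, gj] = df.loc[gj, gi] = v
    return df
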