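"""Dataset loading, the end-to-end pipeline, and the parameter sweep.

A dataset is a directory of protein FASTA files (one per organism) plus
a metadata JSON::

    {
      "schema_version": 1,
      "organisms": [{"organism_id": ..., "fasta_path": ..., "clade": ...}, ...],
      "protein_groups": {"<protein id>": ["membrane", ...], ...}
    }

The pipeline runs vectorize → distance matrix → agglomerative clustering
→ Rand-optimal flattening → Rand index → random-tree significance test,
and the sweep repeats it over a parameter grid with k-mer vectors cached
per (k, alphabet, group) combination.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO

from .agglomerative import LINKAGES, agglomerative_cluster, dendrogram_to_newick
from .distances import METRIC_NAMES, distance_matrix
from .evaluation import (
    empirical_tail_p,
    null_rand_distribution,
    rand_index,
    significance_test,
)
from .kmer_space import (
    CANONICAL_ALPHABET,
    KmerSpec,
    KmerVector,
    ProteinRecord,
    ProteomeRecord,
    REDUCED_ALPHABET,
    group_selector,
    proteome_vector,
    reduce_alphabet,
)
from .tree_flatten import ReferenceClassification, optimal_flat_clustering

logger = logging.getLogger("proteokmer")

__all__ = [
    "read_proteome_fasta",
    "load_dataset",
    "run_pipeline",
    "parameter_sweep",
    "PARAMETER_GRID",
]

#: The full studied parameter grid.
PARAMETER_GRID = {
    "k": (1, 2, 3),
    "alphabet": ("20", "5"),
    "metric": METRIC_NAMES,
    "linkage": LINKAGES,
}

GROUP_CHOICES = (
    "all",
    "membrane",
    "non_membrane",
    "nucleotide_binding",
    "non_nucleotide_binding",
    "ribosomal",
)


def read_proteome_fasta(path: str | Path, organism_id: Optional[str] = None) -> ProteomeRecord:
    """Read one proteome from a multi-record protein FASTA.

    Sequences are upper-cased; the record id (first header token) names
    the protein.  The clade is attached later from metadata.
    """
    path = Path(path)
    proteins = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"{path}: empty sequence for record {record.id!r}")
        proteins.append(ProteinRecord(record.id, seq))
    if not proteins:
        raise ValueError(f"{path}: no FASTA records found")
    return ProteomeRecord(organism_id or path.stem, proteins)


def load_dataset(metadata_path: str | Path) -> tuple[list[ProteomeRecord], ReferenceClassification]:
    """Load all proteomes named in a metadata JSON and build the reference
    classification; group labels are attached to each protein."""
    metadata_path = Path(metadata_path)
    with open(metadata_path) as fh:
        meta = json.load(fh)
    group_map: dict[str, frozenset[str]] = {
        pid: frozenset(groups) for pid, groups in meta.get("protein_groups", {}).items()
    }
    known_ids: set[str] = set()
    proteomes = []
    classes = {}
    for entry in meta["organisms"]:
        oid = entry["organism_id"]
        if oid in classes:
            raise ValueError(f"duplicate organism_id {oid!r} in metadata")
        if not entry.get("clade"):
            raise ValueError(f"organism {oid!r} has no clade label")
        fasta = metadata_path.parent / entry["fasta_path"]
        if not fasta.exists():
            raise FileNotFoundError(f"FASTA for {oid!r} not found: {fasta}")
        proteome = read_proteome_fasta(fasta, organism_id=oid)
        for protein in proteome.proteins:
            protein.groups = group_map.get(protein.id, frozenset())
            known_ids.add(protein.id)
        proteome.clade = entry["clade"]
        proteomes.append(proteome)
        classes[oid] = entry["clade"]
    unknown = set(group_map) - known_ids
    if unknown:
        raise ValueError(
            f"protein_groups references unknown protein ids: {sorted(unknown)[:5]}"
        )
    return proteomes, ReferenceClassification(classes)


def _spec_for(k: int, alphabet: str) -> KmerSpec:
    if alphabet in ("20", "20symbols"):
        return KmerSpec(k, CANONICAL_ALPHABET)
    if alphabet in ("5", "5symbols"):
        return KmerSpec(k, REDUCED_ALPHABET)
    raise ValueError(f"alphabet must be '20' or '5', got {alphabet!r}")


def _group_filter(group: str):
    if group == "all":
        return None
    if group.startswith("non_"):
        return group_selector(exclude=group[4:])
    return group_selector(include=group)


def vectorize_proteomes(
    proteomes: Sequence[ProteomeRecord],
    k: int,
    alphabet: str = "20",
    group: str = "all",
) -> dict[str, KmerVector]:
    """Proteome k-mer vectors for one (k, alphabet, group) combination."""
    spec = _spec_for(k, alphabet)
    reduced = alphabet in ("5", "5symbols")
    filt = _group_filter(group)
    vectors = {}
    for proteome in proteomes:
        if reduced:
            proteome = ProteomeRecord(
                proteome.organism_id,
                [
                    ProteinRecord(p.id, reduce_alphabet(p.sequence), p.groups)
                    for p in proteome.proteins
                ],
                clade=proteome.clade,
            )
        vectors[proteome.organism_id] = proteome_vector(proteome, spec, filt)
    return vectors


def run_pipeline(
    proteomes: Sequence[ProteomeRecord],
    reference: ReferenceClassification,
    k: int = 3,
    alphabet: str = "20",
    group: str = "ribosomal",
    metric: str = "l1",
    linkage: str = "average",
    alpha: float = 0.05,
    n_null_trees: int = 1000,
    seed: int = 0,
    _vectors: Optional[dict[str, KmerVector]] = None,
) -> dict:
    """Vectorize → distances → cluster → flatten → evaluate → null test.

    Returns a JSON-serializable report with the dendrogram (Newick), the
    flat clustering, its Rand index, and the random-tree null threshold.
    Deterministic given `seed`.
    """
    params = {"k": k, "alphabet": alphabet, "group": group,
              "metric": metric, "linkage": linkage, "alpha": alpha,
              "n_null_trees": n_null_trees, "seed": seed}
    logger.info("pipeline start: %s", params)
    vectors = _vectors if _vectors is not None else vectorize_proteomes(
        proteomes, k, alphabet, group
    )
    matrix = distance_matrix(vectors, metric)
    tree = agglomerative_cluster(matrix, linkage)
    clustering = optimal_flat_clustering(tree, reference)
    rand = rand_index(clustering, reference)
    null = null_rand_distribution(reference, n_trees=n_null_trees, alpha=alpha, rng_seed=seed)
    significant, p_value = significance_test(rand, null)
    logger.info("pipeline done: rand=%.4f significant=%s", rand, significant)
    return {
        "parameters": params,
        "newick": dendrogram_to_newick(tree),
        "clustering": dict(sorted(clustering.assignments.items())),
        "n_clusters": len(set(clustering.assignments.values())),
        "rand": rand,
        "null": {
            "mean": null.mean,
            "sd": null.sd,
            "fitted_df": null.fitted_df,
            "fitted_loc": null.fitted_loc,
            "fitted_scale": null.fitted_scale,
            "critical_value": null.critical_value,
        },
        "significant": significant,
        "p_value": p_value,
        "empirical_p": empirical_tail_p(rand, null),
    }


def parameter_sweep(
    proteomes: Sequence[ProteomeRecord],
    reference: ReferenceClassification,
    grid: Optional[dict] = None,
    groups: Sequence[str] = ("all", "ribosomal"),
    alpha: float = 0.05,
    n_null_trees: int = 500,
    seed: int = 0,
) -> list[dict]:
    """Run the pipeline over every grid combination, ranked by Rand.

    k-mer vectors are computed once per (k, alphabet, group) and shared
    across metrics and linkages.  Rows are sorted by Rand descending,
    ties by parameter tuple.
    """
    grid = dict(PARAMETER_GRID if grid is None else grid)
    # one shared null per seed: the null depends only on the reference
    null = null_rand_distribution(reference, n_trees=max(100, n_null_trees), alpha=alpha, rng_seed=seed)
    rows = []
    for k, alphabet, group in itertools.product(grid["k"], grid["alphabet"], groups):
        vectors = vectorize_proteomes(proteomes, k, alphabet, group)
        for metric, linkage in itertools.product(grid["metric"], grid["linkage"]):
            try:
                matrix = distance_matrix(vectors, metric)
                tree = agglomerative_cluster(matrix, linkage)
                clustering = optimal_flat_clustering(tree, reference)
                rand = rand_index(clustering, reference)
            except Exception as exc:
                raise RuntimeError(
                    f"sweep failed at k={k} alphabet={alphabet} group={group} "
                    f"metric={metric} linkage={linkage}: {exc}"
                ) from exc
            significant, p = significance_test(rand, null)
            rows.append({
                "k": k, "alphabet": alphabet, "group": group,
                "metric": metric, "linkage": linkage,
                "rand": rand, "significant": significant, "p_value": p,
            })
    rows.sort(key=lambda r: (-r["rand"], r["k"], r["alphabet"], r["group"], r["metric"], r["linkage"]))
    return rows
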