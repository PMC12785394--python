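"""Synthetic clade-structured proteome generator.

Emulates the study design of a multi-clade bacterial proteome panel with
known ground truth: each clade gets its own residue model (a stationary
amino-acid distribution plus a first-order residue-transition matrix,
drawn from Dirichlet priors centered on uniform), one ancestral proteome
is sampled per clade, and each organism is a point-mutated copy of its
clade ancestor.  First-order Markov generation (rather than i.i.d.
residues) makes 2-mer and 3-mer frequencies carry clade signal beyond
single-residue composition, so the benefit of larger k is exercisable.
Functional protein groups (membrane, ribosomal, nucleotide-binding) are
assigned composition biases so that group-level analyses have signal.

No insertions/deletions are simulated and clades have no internal tree
structure: organisms within a clade are exchangeable mutated copies of
one ancestor, which is all that k-mer composition tests require.
"""

from __future__ import annotations

import json
import textwrap
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np

from .kmer_space import CANONICAL_ALPHABET, ProteinRecord, ProteomeRecord
from .tree_flatten import ReferenceClassification

__all__ = [
    "SimulationConfig",
    "CladeModel",
    "SyntheticDataset",
    "sample_clade_model",
    "generate_dataset",
    "write_dataset",
]

# residue-index sets used for group composition biases
_ALIPHATIC_AROMATIC = [CANONICAL_ALPHABET.index(c) for c in "AILMPVFWY"]
_POSITIVE = [CANONICAL_ALPHABET.index(c) for c in "HKR"]
_GLY_THR_LYS = [CANONICAL_ALPHABET.index(c) for c in "GTK"]

#: Per-group residue up-weighting factors applied to the clade model:
#: membrane proteins favour hydrophobic residues, ribosomal proteins
#: basic residues, nucleotide-binding proteins Walker-motif residues.
GROUP_BIASES: dict[str, tuple[list[int], float]] = {
    "membrane": (_ALIPHATIC_AROMATIC, 2.0),
    "ribosomal": (_POSITIVE, 2.0),
    "nucleotide_binding": (_GLY_THR_LYS, 1.5),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic panel.

    Defaults describe a compact panel with clear clade structure: 6
    clades of 4 organisms, 300 proteins of 150–250 residues each, and a
    5% per-residue mutation rate between an organism and its clade
    ancestor.  ``organisms_per_clade`` may be a range (inclusive) to
    emulate unbalanced clade sizes; ``clade_divergence`` is the Dirichlet
    concentration multiplier — lower values give more divergent clade
    models.
    """

    n_clades: int = 6
    organisms_per_clade: int | tuple[int, int] = 4
    proteins_per_proteome: int = 300
    protein_length: tuple[int, int] = (150, 250)
    clade_divergence: float = 10.0
    mutation_rate: float = 0.05
    group_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"membrane": 0.2, "ribosomal": 0.1, "nucleotide_binding": 0.15}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.n_clades < 1 or self.proteins_per_proteome < 1:
            raise ValueError("counts must be >= 1")
        if sum(self.group_fractions.values()) > 1.0 + 1e-9:
            raise ValueError("group fractions must sum to <= 1")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid protein_length range")

    @property
    def length_range(self) -> tuple[int, int]:
        lr = self.protein_length
        return (lr, lr) if isinstance(lr, int) else tuple(lr)

    @property
    def organisms_range(self) -> tuple[int, int]:
        oc = self.organisms_per_clade
        return (oc, oc) if isinstance(oc, int) else tuple(oc)


@dataclass
class CladeModel:
    """First-order residue model of one clade.

    ``stationary[g]`` and ``transition[g]`` hold the per-group variants
    (key ``None`` is the unlabeled background model).
    """

    stationary: dict[Optional[str], np.ndarray]
    transition: dict[Optional[str], np.ndarray]


@dataclass
class SyntheticDataset:
    proteomes: list[ProteomeRecord]
    reference: ReferenceClassification
    config: SimulationConfig


def _bias_weights(group: Optional[str], n_symbols: int) -> np.ndarray:
    w = np.ones(n_symbols)
    if group in GROUP_BIASES:
        idx, factor = GROUP_BIASES[group]
        w[idx] = factor
    return w


def sample_clade_model(config: SimulationConfig, rng: np.random.Generator) -> CladeModel:
    """Draw one clade's stationary distribution and transition matrix.

    Both are Dirichlet draws centered on uniform with concentration
    ``clade_divergence * |A|``; transition rows are re-centered on the
    clade stationary so the chain mixes to it approximately.  As the
    divergence grows the model converges to the uniform base.
    """
    n = len(CANONICAL_ALPHABET)
    conc = config.clade_divergence * n
    base_stationary = rng.dirichlet(np.full(n, conc / n))
    base_transition = np.stack([rng.dirichlet(conc * base_stationary) for _ in range(n)])
    stationary: dict[Optional[str], np.ndarray] = {}
    transition: dict[Optional[str], np.ndarray] = {}
    for group in [None, *config.group_fractions]:
        w = _bias_weights(group, n)
        s = base_stationary * w
        stationary[group] = s / s.sum()
        t = base_transition * w[None, :]
        transition[group] = t / t.sum(axis=1, keepdims=True)
    return CladeModel(stationary, transition)


def _sample_proteins(
    model: CladeModel,
    groups: list[Optional[str]],
    lengths: np.ndarray,
    rng: np.random.Generator,
) -> list[str]:
    """Sample one Markov-chain protein per (group, length) entry.

    Proteins sharing a group are generated in one vectorized sweep over
    positions.
    """
    n = len(CANONICAL_ALPHABET)
    alphabet = np.frombuffer(CANONICAL_ALPHABET.encode(), dtype=np.uint8)
    out: list[Optional[str]] = [None] * len(groups)
    by_group: dict[Optional[str], list[int]] = {}
    for i, g in enumerate(groups):
        by_group.setdefault(g, []).append(i)
    for g, members in by_group.items():
        stat, trans = model.stationary[g], model.transition[g]
        cum_trans = np.cumsum(trans, axis=1)
        lens = lengths[members]
        max_len = int(lens.max())
        seqs = np.zeros((len(members), max_len), dtype=np.int64)
        seqs[:, 0] = rng.choice(n, size=len(members), p=stat)
        u = rng.random((len(members), max_len))
        for pos in range(1, max_len):
            prev = seqs[:, pos - 1]
            seqs[:, pos] = (u[:, pos, None] > cum_trans[prev]).sum(axis=1)
        for row, i in enumerate(members):
            out[i] = alphabet[seqs[row, : lens[row]]].tobytes().decode()
    return out


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full panel: clades, ancestors, mutated organisms.

    Per clade one ancestral proteome is sampled from the clade model
    (group-specific model for labeled proteins); each organism is a copy
    of the ancestor in which every residue independently mutates with
    probability ``mutation_rate`` to a draw from the clade stationary
    distribution.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = len(CANONICAL_ALPHABET)
    alphabet = np.frombuffer(CANONICAL_ALPHABET.encode(), dtype=np.uint8)
    code = np.full(256, -1, dtype=np.int64)
    for i, ch in enumerate(CANONICAL_ALPHABET):
        code[ord(ch)] = i

    # fixed group layout shared by all proteomes: the first blocks of the
    # protein list carry labels, the remainder is unlabeled background
    group_of: list[Optional[str]] = []
    for g, frac in config.group_fractions.items():
        group_of.extend([g] * int(round(frac * config.proteins_per_proteome)))
    group_of.extend([None] * (config.proteins_per_proteome - len(group_of)))
    group_of = group_of[: config.proteins_per_proteome]

    lo, hi = config.length_range
    olo, ohi = config.organisms_range
    proteomes: list[ProteomeRecord] = []
    classes: dict[str, str] = {}
    for c in range(config.n_clades):
        clade = f"clade{c:02d}"
        model = sample_clade_model(config, rng)
        lengths = rng.integers(lo, hi + 1, size=config.proteins_per_proteome)
        ancestor = _sample_proteins(model, group_of, lengths, rng)
        stat = model.stationary[None]
        n_org = int(rng.integers(olo, ohi + 1))
        for o in range(n_org):
            organism = f"{clade}_org{o}"
            classes[organism] = clade
            proteins = []
            for pi, (seq, group) in enumerate(zip(ancestor, group_of)):
                codes = code[np.frombuffer(seq.encode(), dtype=np.uint8)]
                hit = rng.random(len(codes)) < config.mutation_rate
                if hit.any():
                    codes = codes.copy()
                    codes[hit] = rng.choice(n, size=int(hit.sum()), p=stat)
                proteins.append(
                    ProteinRecord(
                        id=f"{organism}|p{pi:04d}",
                        sequence=alphabet[codes].tobytes().decode(),
                        groups=frozenset() if group is None else frozenset([group]),
                    )
                )
            proteomes.append(ProteomeRecord(organism, proteins, clade=clade))
    return SyntheticDataset(proteomes, ReferenceClassification(classes), config)


def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> Path:
    """Write one FASTA per organism plus a metadata JSON.

    Returns the metadata path.  Re-reading through the dataset loader
    reproduces sequences, clades and group labels exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    organisms = []
    protein_groups: dict[str, list[str]] = {}
    for proteome in dataset.proteomes:
        fasta_name = f"{proteome.organism_id}.fasta"
        with open(directory / fasta_name, "w") as fh:
            for protein in proteome.proteins:
                fh.write(f">{protein.id}\n")
                fh.write(textwrap.fill(protein.sequence, 60) + "\n")
                if protein.groups:
                    protein_groups[protein.id] = sorted(protein.groups)
        organisms.append(
            {"organism_id": proteome.organism_id, "fasta_path": fasta_name,
             "clade": proteome.clade}
        )
    metadata_path = directory / "metadata.json"
    with open(metadata_path, "w") as fh:
        json.dump(
            {"schema_version": 1, "organisms": organisms,
             "protein_groups": protein_groups},
            fh, indent=1,
        )
    return metadata_path
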