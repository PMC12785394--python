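"""Amino-acid k-mer spaces and frequency vectors.

A protein (or a whole proteome) is represented as a normalized frequency
vector over all ``|A|**k`` k-mer types of an ordered alphabet ``A`` —
either the 20 canonical amino acids or a 5-symbol physicochemical
reduction.  Sliding windows that touch any character outside the alphabet
(ambiguity codes such as X/B/Z, the rare residues U/O, gaps, stops)
contribute nothing to the counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "CANONICAL_ALPHABET",
    "REDUCED_ALPHABET",
    "REDUCED_CLASSES",
    "KmerSpec",
    "ProteinRecord",
    "ProteomeRecord",
    "KmerVector",
    "reduce_alphabet",
    "count_kmers",
    "protein_vector",
    "proteome_vector",
]

#: The 20 canonical amino acids in lexicographic one-letter order.
CANONICAL_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Physicochemical classes, in declaration order: aliphatic, aromatic,
#: uncharged, positively charged, negatively charged.
REDUCED_CLASSES = {
    "1": "AILMPV",   # aliphatic
    "2": "FWY",      # aromatic
    "3": "CGNQST",   # uncharged
    "4": "HKR",      # positively charged
    "5": "DE",       # negatively charged
}

#: Ordered symbols of the 5-class reduced alphabet.
REDUCED_ALPHABET = "12345"

_REDUCTION_TABLE = {aa: cls for cls, members in REDUCED_CLASSES.items() for aa in members}

MAX_K = 4


@dataclass(frozen=True)
class KmerSpec:
    """Configuration fixing the k-mer vector space.

    Parameters
    ----------
    k
        Window length; 1–4 supported.  k-mer vectors over bacterial
        proteomes become very sparse beyond k = 3, so k = 4 triggers a
        sparsity warning.
    alphabet
        Ordered symbol string; the position of every length-k string over
        it (in lexicographic order of the declared symbol order) defines
        the vector dimension ``n = len(alphabet) ** k``.
    """

    k: int
    alphabet: str = CANONICAL_ALPHABET

    def __post_init__(self) -> None:
        if not (1 <= self.k <= MAX_K):
            raise ValueError(f"k must be in 1..{MAX_K}, got {self.k}")
        if len(set(self.alphabet)) != len(self.alphabet) or not self.alphabet:
            raise ValueError("alphabet must be a non-empty string of unique symbols")
        if self.k == MAX_K:
            warnings.warn(
                "k=4 vectors are extremely sparse for bacterial proteomes; "
                "k<=3 is recommended",
                stacklevel=2,
            )

    @property
    def n(self) -> int:
        """Vector dimension ``|alphabet| ** k``."""
        return len(self.alphabet) ** self.k

    def kmer_index(self, kmer: str) -> int:
        """Position of `kmer` in the canonical (lexicographic) ordering."""
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got {kmer!r}")
        base = len(self.alphabet)
        idx = 0
        for ch in kmer:
            pos = self.alphabet.find(ch)
            if pos < 0:
                raise KeyError(f"symbol {ch!r} not in alphabet")
            idx = idx * base + pos
        return idx

    def index_kmer(self, index: int) -> str:
        """Inverse of :meth:`kmer_index`."""
        if not (0 <= index < self.n):
            raise IndexError(index)
        base = len(self.alphabet)
        out = []
        for _ in range(self.k):
            index, rem = divmod(index, base)
            out.append(self.alphabet[rem])
        return "".join(reversed(out))

    def _code_table(self) -> np.ndarray:
        table = np.full(256, -1, dtype=np.int64)
        for i, ch in enumerate(self.alphabet):
            table[ord(ch)] = i
        return table


@dataclass
class ProteinRecord:
    """A single protein: identifier, sequence, and functional-group labels."""

    id: str
    sequence: str
    groups: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        self.groups = frozenset(self.groups)


@dataclass
class ProteomeRecord:
    """All proteins of one organism plus its reference clade label."""

    organism_id: str
    proteins: list[ProteinRecord]
    clade: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ValueError(f"proteome {self.organism_id!r} has no proteins")

    def __len__(self) -> int:
        return len(self.proteins)


@dataclass
class KmerVector:
    """Normalized k-mer frequency vector.

    ``values`` sums to 1 whenever ``total_kmers > 0`` and is all-zero
    otherwise; ``total_kmers`` is the pooled raw count before
    normalization.
    """

    spec: KmerSpec
    values: np.ndarray
    total_kmers: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.spec.n,):
            raise ValueError(
                f"expected {self.spec.n} values, got shape {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("frequencies must be non-negative")
        if self.total_kmers > 0 and abs(self.values.sum() - 1.0) > 1e-9:
            raise ValueError("non-empty frequency vector must sum to 1")


def reduce_alphabet(sequence: str) -> str:
    """Recode a 20-letter amino-acid sequence into 5 physicochemical classes.

    Characters without a class (ambiguity codes, U/O, gaps) pass through
    unchanged; they are discarded later at counting time.

    >>> reduce_alphabet("ALWKD")
    '11245'
    """
    return "".join(_REDUCTION_TABLE.get(ch, ch) for ch in sequence)


def count_kmers(sequence: str, spec: KmerSpec) -> np.ndarray:
    """Count every overlapping k-mer window of `sequence`.

    Windows containing any symbol outside ``spec.alphabet`` are skipped
    entirely.  A sequence shorter than k yields all-zero counts.
    """
    counts = np.zeros(spec.n, dtype=np.int64)
    _accumulate_counts(sequence, spec, counts)
    return counts


def _accumulate_counts(sequence: str, spec: KmerSpec, counts: np.ndarray) -> None:
    k = spec.k
    if len(sequence) < k:
        return
    codes = spec._code_table()[np.frombuffer(sequence.encode("latin-1"), dtype=np.uint8)]
    valid = codes >= 0
    base = len(spec.alphabet)
    n_win = len(sequence) - k + 1
    idx = np.zeros(n_win, dtype=np.int64)
    ok = np.ones(n_win, dtype=bool)
    for j in range(k):
        idx = idx * base + codes[j : j + n_win]
        ok &= valid[j : j + n_win]
    np.add.at(counts, idx[ok], 1)


def _normalize(counts: np.ndarray, spec: KmerSpec) -> KmerVector:
    total = int(counts.sum())
    if total == 0:
        return KmerVector(spec, np.zeros(spec.n), 0)
    return KmerVector(spec, counts / total, total)


def protein_vector(protein: ProteinRecord, spec: KmerSpec) -> KmerVector:
    """Frequency vector of one protein: ``p_i = c_i / sum_j c_j``."""
    return _normalize(count_kmers(protein.sequence, spec), spec)


GroupFilter = Callable[[ProteinRecord], bool]


def group_selector(include: Optional[str] = None, exclude: Optional[str] = None) -> GroupFilter:
    """Build a protein filter: keep members of `include`, or non-members of `exclude`."""
    if include is not None and exclude is not None:
        raise ValueError("give either include or exclude, not both")
    if include is not None:
        return lambda p: include in p.groups
    if exclude is not None:
        return lambda p: exclude not in p.groups
    return lambda p: True


def proteome_vector(
    proteome: ProteomeRecord,
    spec: KmerSpec,
    group_filter: Optional[GroupFilter] = None,
) -> KmerVector:
    """Pooled frequency vector of a proteome.

    Raw counts are pooled across the selected proteins *before*
    normalization (length-weighted), not averaged per protein:
    ``P_i = sum_j c_ij / sum_i sum_j c_ij``.
    """
    selected = [p for p in proteome.proteins if group_filter is None or group_filter(p)]
    if not selected:
        raise ValueError(
            f"group filter selected no proteins in proteome {proteome.organism_id!r}"
        )
    counts = np.zeros(spec.n, dtype=np.int64)
    for protein in selected:
        _accumulate_counts(protein.sequence, spec, counts)
    return _normalize(counts, spec)
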