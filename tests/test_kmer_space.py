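"""Alphabet reduction, k-mer counting, and frequency-vector construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proteokmer.kmer_space import (
    CANONICAL_ALPHABET,
    REDUCED_ALPHABET,
    REDUCED_CLASSES,
    KmerSpec,
    ProteinRecord,
    ProteomeRecord,
    count_kmers,
    group_selector,
    protein_vector,
    proteome_vector,
    reduce_alphabet,
)

protein_seq = st.text(alphabet=CANONICAL_ALPHABET, min_size=0, max_size=60)


class TestKmerSpec:
    @pytest.mark.parametrize(
        "k,alphabet,n",
        [(3, CANONICAL_ALPHABET, 8000), (3, REDUCED_ALPHABET, 125),
         (1, CANONICAL_ALPHABET, 20), (2, "AC", 4)],
    )
    def test_dimension(self, k, alphabet, n):
        assert KmerSpec(k, alphabet).n == n

    def test_index_is_lexicographic_bijection(self):
        spec = KmerSpec(2, "ACD")
        kmers = [spec.index_kmer(i) for i in range(spec.n)]
        assert kmers == sorted(kmers)  # lexicographic in declared order
        assert len(set(kmers)) == spec.n
        assert all(spec.kmer_index(km) == i for i, km in enumerate(kmers))

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            KmerSpec(0)
        with pytest.raises(ValueError):
            KmerSpec(5)

    def test_k4_warns_about_sparsity(self):
        with pytest.warns(UserWarning):
            KmerSpec(4)


class TestReduceAlphabet:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ALWKD", "11245"), ("", ""), ("DE", "55"),
         ("AXU", "1XU")],  # unmapped characters pass through
    )
    def test_examples(self, seq, expected):
        assert reduce_alphabet(seq) == expected

    def test_classes_cover_canonical_alphabet_exactly(self):
        members = "".join(REDUCED_CLASSES.values())
        assert sorted(members) == sorted(CANONICAL_ALPHABET)

    @given(protein_seq)
    def test_preserves_length(self, seq):
        assert len(reduce_alphabet(seq)) == len(seq)


class TestCountKmers:
    def test_sliding_window(self):
        spec = KmerSpec(3)
        counts = count_kmers("ACDEF", spec)
        assert counts.sum() == 3
        for km in ("ACD", "CDE", "DEF"):
            assert counts[spec.kmer_index(km)] == 1

    @pytest.mark.parametrize("seq", ["AXA", "AUA", "A-A", "ABA"])
    def test_windows_with_noncanonical_residues_skipped(self, seq):
        assert count_kmers(seq, KmerSpec(2)).sum() == 0

    def test_short_sequence_gives_zeros(self):
        assert count_kmers("AC", KmerSpec(3)).sum() == 0

    def test_k1_counts_residues(self):
        spec = KmerSpec(1)
        counts = count_kmers("AAA", spec)
        assert counts[spec.kmer_index("A")] == 3 and counts.sum() == 3

    @given(st.text(alphabet=CANONICAL_ALPHABET + "XU-", min_size=0, max_size=50),
           st.integers(1, 3))
    @settings(max_examples=200)
    def test_count_conservation_vs_window_scan(self, seq, k):
        """Total counts equal a direct scan over valid windows."""
        spec = KmerSpec(k)
        expected = sum(
            1
            for i in range(max(0, len(seq) - k + 1))
            if all(ch in CANONICAL_ALPHABET for ch in seq[i : i + k])
        )
        assert count_kmers(seq, spec).sum() == expected

    @given(protein_seq, st.integers(1, 3))
    @settings(max_examples=100)
    def test_reduction_commutes_with_counting(self, seq, k):
        """Counting on the reduced sequence equals reducing each 20-alphabet
        k-mer and summing its counts."""
        full = KmerSpec(k, CANONICAL_ALPHABET)
        red = KmerSpec(k, REDUCED_ALPHABET)
        direct = count_kmers(reduce_alphabet(seq), red)
        summed = np.zeros(red.n, dtype=np.int64)
        counts = count_kmers(seq, full)
        for i in np.nonzero(counts)[0]:
            summed[red.kmer_index(reduce_alphabet(full.index_kmer(int(i))))] += counts[i]
        assert np.array_equal(direct, summed)


class TestVectors:
    def test_protein_vector_normalizes(self):
        v = protein_vector(ProteinRecord("p", "ACAC"), KmerSpec(2))
        spec = v.spec
        assert v.total_kmers == 3
        assert v.values[spec.kmer_index("AC")] == pytest.approx(2 / 3)
        assert v.values[spec.kmer_index("CA")] == pytest.approx(1 / 3)

    def test_no_valid_kmers_gives_zero_vector(self):
        v = protein_vector(ProteinRecord("p", "XXXX"), KmerSpec(2))
        assert v.total_kmers == 0 and not v.values.any()

    def test_proteome_pools_counts_before_normalizing(self):
        proteome = ProteomeRecord(
            "o", [ProteinRecord("a", "AAC"), ProteinRecord("b", "CA")]
        )
        v = proteome_vector(proteome, KmerSpec(2))
        spec = v.spec
        assert v.total_kmers == 3
        for km in ("AA", "AC", "CA"):
            assert v.values[spec.kmer_index(km)] == pytest.approx(1 / 3)

    def test_pooling_is_length_weighted_not_mean_of_vectors(self):
        # one long A-protein and one short C-protein: pooled frequency of A
        # reflects the raw count ratio 9:1, not the (1/2, 1/2) vector mean
        proteome = ProteomeRecord(
            "o", [ProteinRecord("a", "A" * 9), ProteinRecord("b", "C")]
        )
        v = proteome_vector(proteome, KmerSpec(1))
        assert v.values[v.spec.kmer_index("A")] == pytest.approx(0.9)

    def test_single_protein_proteome_equals_protein_vector(self):
        protein = ProteinRecord("a", "ACDEFG")
        spec = KmerSpec(2)
        got = proteome_vector(ProteomeRecord("o", [protein]), spec)
        expected = protein_vector(protein, spec)
        assert np.allclose(got.values, expected.values)

    def test_group_filters(self):
        proteome = ProteomeRecord(
            "o",
            [ProteinRecord("a", "AA", groups={"g1"}),
             ProteinRecord("b", "CC", groups={"g2"})],
        )
        spec = KmerSpec(1)
        v = proteome_vector(proteome, spec, group_selector(include="g1"))
        assert v.values[spec.kmer_index("A")] == 1.0
        v = proteome_vector(proteome, spec, group_selector(exclude="g1"))
        assert v.values[spec.kmer_index("C")] == 1.0
        with pytest.raises(ValueError, match="no proteins"):
            proteome_vector(proteome, spec, group_selector(include="missing"))

    @given(st.lists(protein_seq.filter(bool), min_size=1, max_size=5), st.integers(1, 3))
    @settings(max_examples=100)
    def test_normalization_invariant(self, seqs, k):
        proteome = ProteomeRecord(
            "o", [ProteinRecord(f"p{i}", s) for i, s in enumerate(seqs)]
        )
        v = proteome_vector(proteome, KmerSpec(k))
        if v.total_kmers > 0:
            assert abs(v.values.sum() - 1.0) < 1e-9
        else:
            assert not v.values.any()
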