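import numpy as np
import pytest

from proteokmer.kmer_space import CANONICAL_ALPHABET, KmerSpec, KmerVector


def make_vector(values, alphabet=None) -> KmerVector:
    """KmerVector over a k=1 alphabet sized to the value list.

    Accepts raw non-negative weights and normalizes them; an all-zero
    list yields the empty vector.
    """
    values = np.asarray(values, dtype=float)
    alphabet = alphabet or CANONICAL_ALPHABET[: len(values)]
    spec = KmerSpec(1, alphabet)
    total = values.sum()
    if total == 0:
        return KmerVector(spec, values, 0)
    return KmerVector(spec, values / total, int(round(total)))


def random_prob_vector(rng, n, alphabet=None) -> KmerVector:
    return make_vector(rng.random(n) + 1e-12, alphabet=alphabet)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
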