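import numpy as np
import pytest

from seqkernel import (
    AminoAlphabet,
    KernelParams,
    RatioMatrix,
    load_default_counts,
    normalize_counts,
)
from seqkernel.synthdata import random_sequence


@pytest.fixture(scope="session")
def sm2():
    """Odds-ratio matrix from the packaged synthetic count table."""
    return normalize_counts(load_default_counts())


@pytest.fixture(scope="session")
def default_params(sm2):
    """The recommended kernel setting: beta=0.2, k_max=10."""
    return KernelParams(sm2, beta=0.2, k_max=10)


@pytest.fixture(scope="session")
def toy_alphabet():
    return AminoAlphabet(("A", "B"))


@pytest.fixture(scope="session")
def toy_k1(toy_alphabet):
    """A 2-letter residue kernel [[4,1],[1,4]] with beta already applied."""
    return RatioMatrix(np.array([[4.0, 1.0], [1.0, 4.0]]), toy_alphabet, beta_applied=1.0)


def make_random_sequences(n, rng, min_len=30, max_len=120, prefix="s"):
    return [
        random_sequence(int(rng.integers(min_len, max_len + 1)), rng, f"{prefix}{i}")
        for i in range(n)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
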