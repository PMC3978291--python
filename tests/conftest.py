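import numpy as np
import pytest

from symcomplex.sequences import ALPHABET, SymbolSequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_sequence(rng):
    """A generic 4-symbol random sequence of moderate length."""
    return SymbolSequence("".join(rng.choice(list(ALPHABET), size=2000)))


def make_random_string(rng, alphabet: str, n: int) -> str:
    return "".join(rng.choice(list(alphabet), size=n))
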