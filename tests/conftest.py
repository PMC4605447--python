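import numpy as np
import pytest

from lingo_mcc import Compound, SynthSpec, gen_library

# Small alphabet so random string pairs actually share q-grams.
SMALL_ALPHABET = "CNOc1(=)"


def random_smiles(rng: np.random.Generator, max_len: int = 200, min_len: int = 0,
                  alphabet: str = SMALL_ALPHABET) -> str:
    n = int(rng.integers(min_len, max_len + 1))
    return "".join(rng.choice(list(alphabet), size=n)) if n else ""


def distinct_window_string(rng: np.random.Generator, length: int = 13, q: int = 4) -> str:
    """A random `length`-char ASCII string whose q-windows are pairwise distinct."""
    letters = list("ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz")
    while True:
        s = "".join(rng.choice(letters, size=length))
        windows = [s[i:i + q] for i in range(length - q + 1)]
        if len(set(windows)) == len(windows):
            return s


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)


@pytest.fixture
def tiny_library() -> list[Compound]:
    spec = SynthSpec(n=5, length_dist="uniform", params=(10, 30), seed=7)
    return gen_library(spec)
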