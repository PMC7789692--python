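import numpy as np
import pytest

from tricgen import Alphabet, BackgroundSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def real_alphabet():
    return Alphabet(kind="real", min_value=-100.0, max_value=100.0)


@pytest.fixture
def integer_alphabet():
    return Alphabet(kind="integer", min_value=0, max_value=9)


@pytest.fixture
def symbolic_alphabet():
    return Alphabet(kind="symbolic", symbols=tuple("abcde"))


@pytest.fixture
def uniform_background():
    return BackgroundSpec(family="uniform")


def small_config(**overrides):
    """A minimal integer-dataset configuration dict for end-to-end tests."""
    cfg = {
        "dataset": {
            "dtype": "integer",
            "dims": [12, 10, 6],
            "alphabet": {"min": 0, "max": 50},
            "background": {"family": "uniform"},
        },
        "triclusters": {
            "n": 2,
            "rows": {"dist": "uniform", "a": 3, "b": 4},
            "cols": {"dist": "uniform", "a": 2, "b": 3},
            "ctxs": {"dist": "uniform", "a": 2, "b": 2},
            "patterns": "all",
        },
    }
    for key, val in overrides.items():
        cfg[key] = val
    return cfg
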