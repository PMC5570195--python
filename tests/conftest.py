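import numpy as np
import pytest

from motifcore import Alphabet, EncodingScheme, IndelPolicy, TrainConfig


@pytest.fixture
def aa():
    return Alphabet.amino_acid()


@pytest.fixture
def dna():
    return Alphabet.dna()


@pytest.fixture
def abc():
    """Tiny 3-letter alphabet used by the enumeration oracles."""
    return Alphabet.from_string("ABC", wildcard="X")


@pytest.fixture
def fast_config():
    """Small training configuration that keeps unit tests quick."""
    return TrainConfig(hidden_sizes=(4,), n_seeds=1, learning_rate=0.1, epochs=40, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return path
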