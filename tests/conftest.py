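import numpy as np
import pytest

from ribodigest.digestion import BUILTIN_ENZYMES


@pytest.fixture
def hrnase4():
    return BUILTIN_ENZYMES["hRNase4"]


@pytest.fixture
def rnaset1():
    return BUILTIN_ENZYMES["RNaseT1"]


@pytest.fixture
def rng():
    return np.random.default_rng(20220725)


def random_rna(rng, length):
    return tuple(rng.choice(["A", "C", "G", "U"], size=length))


@pytest.fixture
def random_seq(rng):
    return random_rna(rng, 200)
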