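import numpy as np
import pytest

from tevar.types import GenomeSequence


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_genome(rng, length, gc=0.42, name="chr1"):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(list("ACGT"), size=length, p=p))
    return GenomeSequence({name: seq})


@pytest.fixture
def small_genome(rng):
    return random_genome(rng, 3000)
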