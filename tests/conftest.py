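import numpy as np
import pytest

from evofoot.seqio import SeqRecord


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def ref300(rng) -> SeqRecord:
    return SeqRecord("ref", random_dna(rng, 300))
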