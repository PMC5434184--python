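import numpy as np
import pytest

from l1peak import synth
from l1peak.core import GenomicInterval, ReferenceGenome
from l1peak.reads import AmpliconRead


@pytest.fixture(scope="session")
def small_genome() -> ReferenceGenome:
    return synth.generate_genome(50_000, gc_fraction=0.45, seed=11)


@pytest.fixture(scope="session")
def pools():
    return synth.default_pools()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_read(seq: str, qual: int = 37, read_id: str = "r") -> AmpliconRead:
    return AmpliconRead(read_id, seq, tuple([qual] * len(seq)))


@pytest.fixture()
def read_factory():
    return make_read
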