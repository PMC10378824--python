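import numpy as np
import pytest

from sbscan.synth_data import GenomeSpec, generate


@pytest.fixture(scope="session")
def group1_genome():
    """One group-1-like synthetic genome with its truth record."""
    return generate(GenomeSpec(mode="GROUP1", seed=7))


@pytest.fixture(scope="session")
def group2_genome():
    return generate(GenomeSpec(mode="GROUP2", seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
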