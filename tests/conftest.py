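import numpy as np
import pytest

from v2gmap.synthetic_data import SimConfig, simulate_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_fixture():
    """The default planted fixture (seed 7), shared across test modules."""
    return simulate_fixture(SimConfig(seed=7))


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000, max_len=300):
    """Unsorted random intervals for oracle-equivalence tests."""
    from v2gmap.genomic_core import GenomicInterval

    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(str(rng.choice(chroms)), start, start + length))
    return out
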