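import numpy as np
import pytest

from subseqhash.order import generate_tables


@pytest.fixture
def rng():
    return np.random.default_rng(20230601)


@pytest.fixture(scope="session")
def tables_k4():
    """Small ABC order used across tests (k=4, d=11)."""
    return generate_tables(k=4, d=11, seed=7)


def random_dna(rng, length):
    return "".join("ACGT"[c] for c in rng.integers(0, 4, length))
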