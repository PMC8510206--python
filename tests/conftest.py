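import numpy as np
import pytest
from hypothesis import settings

from pepscreen.digestion import ProteinRecord

settings.register_profile("stable", derandomize=True)
settings.load_profile("stable")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_proteome(rng):
    """A handful of random proteins over the 20-letter alphabet."""
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    records = []
    for i in range(10):
        n = int(rng.integers(40, 200))
        records.append(
            ProteinRecord(f"prot{i}", "".join(letters[rng.integers(0, 20, n)]))
        )
    return records


def random_peptide(rng, min_len=5, max_len=30):
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    n = int(rng.integers(min_len, max_len + 1))
    return "".join(letters[rng.integers(0, 20, n)])
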