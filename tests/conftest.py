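import random
import string

import numpy as np
import pytest

from repchimera import Alignment, RunConfig, SequenceRecord, SimSpec, simulate_dataset
from repchimera.io import AMINO_ACIDS


@pytest.fixture(scope="session")
def default_sim():
    """One simulated family with planted chimeras, shared across tests."""
    spec = SimSpec(seed=1, chimera_fraction=0.3)
    records, truth, tree = simulate_dataset(spec)
    return spec, records, truth, tree


@pytest.fixture(scope="session")
def default_alignment(default_sim):
    _, records, _, _ = default_sim
    return Alignment(tuple(records))


def random_records(rng: random.Random, n: int, length: int, prefix: str = "s"):
    """Unrelated random protein records (no shared ancestry)."""
    return [
        SequenceRecord(
            f"{prefix}{i:03d}",
            "".join(rng.choice(AMINO_ACIDS) for _ in range(length)),
        )
        for i in range(n)
    ]


@pytest.fixture
def rng():
    return random.Random(20240917)
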