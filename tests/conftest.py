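import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from nanoampsim import (
    MOCK8_ABUNDANCES,
    ProfileEntry,
    generate_amplicons,
    generate_references,
)

SEED = 20230912


@pytest.fixture(scope="session")
def mock_refs():
    """Eight synthetic ~16S references mirroring an 8-species mock community."""
    return generate_references(
        8, 1500, 0.05, SEED, taxon_ids=list(MOCK8_ABUNDANCES)
    )


@pytest.fixture(scope="session")
def small_amplicons(mock_refs):
    """1000 error-free full-length amplicon reads from the mock profile."""
    return generate_amplicons(mock_refs, MOCK8_ABUNDANCES, 1000, SEED + 1)


@pytest.fixture
def flat_profile():
    """A profile factory: n identical entries at a given total rate."""

    def make(n, rate=10.0, split=(0.28, 0.42, 0.30)):
        return [
            ProfileEntry(rate * split[0], rate * split[1], rate * split[2])
            for _ in range(n)
        ]

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
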