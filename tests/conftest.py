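import numpy as np
import pytest

from fuzzyseed.core_hashing import SimHashConfig
from fuzzyseed.seeding import SeedingParams


@pytest.fixture
def cfg64():
    return SimHashConfig(b=64)


@pytest.fixture
def blend_i_params():
    return SeedingParams(mode="blend_i", seed_len=15, neighbors=5, window=10)


@pytest.fixture
def baseline_params():
    return SeedingParams(mode="baseline", seed_len=15, neighbors=5, window=10)


@pytest.fixture
def blend_s_params():
    return SeedingParams(mode="blend_s", k=19, neighbors=5, window=50)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def naive_simhash(items, b):
    """Independent per-bit counting oracle for the SimHash majority vote."""
    out = 0
    for t in range(b):
        ones = sum((x >> t) & 1 for x in items)
        zeros = len(items) - ones
        if ones > zeros:
            out |= 1 << t
    return out


def random_multisets(rng, count, max_size=64, widths=(8, 16, 32, 64)):
    """Random (items, b) cases spanning sizes 1..max_size and several widths."""
    cases = []
    for _ in range(count):
        b = int(rng.choice(widths))
        size = int(rng.integers(1, max_size + 1))
        items = [int(x) for x in rng.integers(0, 2**b, size=size, dtype=np.uint64)]
        cases.append((items, b))
    return cases
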