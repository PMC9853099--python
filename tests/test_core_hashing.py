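"""Unit and property tests for k-mer packing and the SimHash majority vote."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fuzzyseed.core_hashing import (
    AmbiguousBaseError,
    EmptySetError,
    ItemOverflowError,
    KmerCode,
    SimHashConfig,
    base_hash,
    base_hash_vec,
    canonical,
    counter_vector,
    pack_kmer,
    revcomp,
    revcomp_vec,
    simhash,
    simhash_rows,
    simhash_windows,
    unpack_kmer,
)
from conftest import naive_simhash, random_multisets


@pytest.mark.parametrize(
    "window,value",
    [("ACG", 0b000110), ("AAAA", 0), ("CGT", (1 << 4) | (2 << 2) | 3), ("acg", 6)],
)
def test_pack_kmer_examples(window, value):
    code = pack_kmer(window)
    assert code.value == value
    assert code.k == len(window)
    assert unpack_kmer(code) == window.upper()


def test_pack_kmer_rejects_ambiguous_bases():
    with pytest.raises(AmbiguousBaseError):
        pack_kmer("ACNG")
    with pytest.raises(AmbiguousBaseError):
        pack_kmer("ACRG")


def test_kmercode_value_range_enforced():
    with pytest.raises(ValueError):
        KmerCode(value=4**3, k=3)


@settings(derandomize=True, max_examples=200, deadline=None)
@given(st.integers(1, 32), st.data())
def test_revcomp_is_an_involution(k, data):
    value = data.draw(st.integers(0, 4**k - 1))
    code = KmerCode(value=value, k=k)
    assert revcomp(revcomp(code)).value == code.value


def test_canonical_examples():
    fwd = canonical("ACG")
    assert (fwd.value, fwd.strand) == (6, "+")
    rev = canonical("CGT")
    assert (rev.value, rev.strand) == (6, "-")
    pal = canonical("ACGT")
    assert pal.palindromic


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.integers(1, 20), st.data())
def test_canonical_is_strand_independent(k, data):
    value = data.draw(st.integers(0, 4**k - 1))
    code = KmerCode(value=value, k=k)
    assert canonical(code).value == canonical(revcomp(code)).value


def test_base_hash_is_deterministic_and_distinct_at_full_width():
    cfg = SimHashConfig(b=64, hash_seed=7)
    values = np.arange(4**8, dtype=np.uint64)
    hashes = base_hash_vec(values, cfg)
    # invertible finalizer: all 4^8 8-mers map to distinct 64-bit values
    assert len(np.unique(hashes)) == len(values)
    assert base_hash(KmerCode(123, 8), cfg) == base_hash(KmerCode(123, 8), cfg)
    assert int(hashes[123]) == base_hash(KmerCode(123, 8), cfg)


def test_base_hash_depends_on_seed(rng):
    codes = rng.integers(0, 4**15, size=1000, dtype=np.uint64)
    a = base_hash_vec(codes, SimHashConfig(b=64, hash_seed=0))
    b = base_hash_vec(codes, SimHashConfig(b=64, hash_seed=1))
    assert (a != b).any()


def test_revcomp_vec_matches_scalar(rng):
    for k in (4, 11, 15, 31):
        values = rng.integers(0, 4**k, size=200, dtype=np.uint64)
        vec = revcomp_vec(values, k)
        for v, r in zip(values[:50], vec[:50]):
            assert int(r) == revcomp(KmerCode(int(v), k)).value


def test_simhash_examples():
    cfg4 = SimHashConfig(b=4)
    assert simhash([0b1100, 0b1010, 0b1001], cfg4) == 0b1000
    assert simhash([0b11, 0b00], SimHashConfig(b=2)) == 0b00  # all ties -> 0
    cfg = SimHashConfig(b=64)
    for x in (0, 1, 2**63, 12345):
        assert simhash([x], cfg) == x  # single item: sign matches the bit


def test_simhash_error_conditions():
    cfg = SimHashConfig(b=8)
    with pytest.raises(EmptySetError):
        simhash([], cfg)
    with pytest.raises(ItemOverflowError):
        simhash([256], cfg)


def test_simhash_matches_naive_counting_oracle(rng):
    for items, b in random_multisets(rng, 2000):
        cfg = SimHashConfig(b=b)
        assert simhash(items, cfg) == naive_simhash(items, b)


def test_simhash_vectorized_paths_match_scalar(rng):
    cfg = SimHashConfig(b=32)
    hashes = rng.integers(0, 2**32, size=50, dtype=np.uint64)
    n = 5
    windows = simhash_windows(hashes, n, cfg)
    rows = simhash_rows(
        np.lib.stride_tricks.sliding_window_view(hashes, n).astype(np.uint64), cfg
    )
    for i in range(len(hashes) - n + 1):
        expected = simhash([int(x) for x in hashes[i:i + n]], cfg)
        assert int(windows[i]) == expected
        assert int(rows[i]) == expected


@settings(derandomize=True, max_examples=150, deadline=None)
@given(
    st.lists(st.integers(0, 2**16 - 1), min_size=1, max_size=20),
    st.randoms(use_true_random=False),
)
def test_simhash_is_permutation_invariant(items, rnd):
    cfg = SimHashConfig(b=16)
    shuffled = list(items)
    rnd.shuffle(shuffled)
    assert simhash(items, cfg) == simhash(shuffled, cfg)


@pytest.mark.parametrize("m", [1, 2, 3, 17])
def test_uniform_multiset_hashes_to_its_item(m):
    cfg = SimHashConfig(b=32)
    x = 0xDEADBEEF
    assert simhash([x] * m, cfg) == x


@settings(derandomize=True, max_examples=150, deadline=None)
@given(st.lists(st.integers(0, 2**16 - 1), min_size=1, max_size=21))
def test_complement_symmetry_for_odd_sizes(items):
    # odd multiset size: every counter is nonzero, so the tie rule never
    # fires and complementing all items complements the hash
    if len(items) % 2 == 0:
        items = items[:-1]
    cfg = SimHashConfig(b=16)
    mask = cfg.mask
    complemented = [x ^ mask for x in items]
    assert simhash(complemented, cfg) == (simhash(items, cfg) ^ mask)


def test_counter_stability_under_single_item_replacement(rng):
    cfg = SimHashConfig(b=16)
    for _ in range(50):
        size = int(rng.integers(2, 33))
        items = [int(x) for x in rng.integers(0, 2**16, size=size)]
        replaced = list(items)
        replaced[0] = int(rng.integers(0, 2**16))
        before = counter_vector(items, cfg)
        after = counter_vector(replaced, cfg)
        for t, (c0, c1) in enumerate(zip(before, after)):
            assert abs(c1 - c0) <= 2
            if abs(c0) > 2:  # a solid majority survives one replacement
                assert (c0 > 0) == (c1 > 0)


def test_counter_parity_matches_multiset_size(rng):
    cfg = SimHashConfig(b=8)
    for size in (1, 2, 5, 8):
        items = [int(x) for x in rng.integers(0, 256, size=size)]
        counts = counter_vector(items, cfg)
        assert all(abs(c) <= size and (c - size) % 2 == 0 for c in counts)
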