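"""Bit-level k-mer encoding, a seedable low-collision hash, and the SimHash core.

A k-mer is packed into an unsigned integer of 2k bits (A=0, C=1, G=2, T=3,
most-significant pair = first base).  The low-collision *base hash* is an
invertible 64-bit mixing finalizer (splitmix64 family): for a fixed seed it
is a bijection on 64-bit words, so distinct k-mer codes can only collide
after truncation to fewer than 64 bits.

The SimHash of a multiset of b-bit item hashes is computed in three steps:

1. *encode* -- each item hash becomes a vector of b elements, +1 where the
   corresponding bit is 1 and -1 where it is 0;
2. *sum* -- the vectors are added element-wise into a *counter vector*, so
   ``counts[t] = (#items with bit t set) - (#items with bit t clear)``,
   counting multiplicity;
3. *decode* -- output bit t is 1 iff ``counts[t] > 0`` (ties decode to 0).

Because a few differing items rarely flip a majority, highly similar
multisets -- hence highly similar seeds -- receive identical hash values.

Bit position t = 0 is the least-significant bit throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

FORWARD = "+"
REVERSE = "-"

_MASK64 = 0xFFFFFFFFFFFFFFFF
_GOLDEN = 0x9E3779B97F4A7C15

_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3,
           "a": 0, "c": 1, "g": 2, "t": 3}
_DECODE = "ACGT"


class AmbiguousBaseError(ValueError):
    """Window contains a base outside A/C/G/T (unpackable window)."""


class EmptySetError(ValueError):
    """SimHash requested for an empty multiset."""


class ItemOverflowError(ValueError):
    """A SimHash item exceeds the configured bit width."""


@dataclass(frozen=True)
class KmerCode:
    """A 2-bit-packed nucleotide word with strand orientation.

    ``value`` holds the packed word (first base in the most-significant
    bit pair); ``strand`` records which orientation the value represents.
    ``palindromic`` marks words equal to their own reverse complement
    (only possible for even k).
    """

    value: int
    k: int
    strand: str = FORWARD
    palindromic: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 32:
            raise ValueError(f"k must be in [1, 32], got {self.k}")
        if not 0 <= self.value < 4 ** self.k:
            raise ValueError(f"code value {self.value} out of range for k={self.k}")
        if self.strand not in (FORWARD, REVERSE):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


def pack_kmer(window: str) -> KmerCode:
    """Pack a nucleotide string into its forward-strand :class:`KmerCode`.

    Raises :class:`AmbiguousBaseError` on N or any other non-ACGT symbol;
    callers skip the seed containing such a window.
    """
    value = 0
    for ch in window:
        code = _ENCODE.get(ch)
        if code is None:
            raise AmbiguousBaseError(f"unpackable window: ambiguous base {ch!r}")
        value = (value << 2) | code
    if not window:
        raise ValueError("empty window")
    return KmerCode(value=value, k=len(window))


def unpack_kmer(code: KmerCode) -> str:
    out = []
    for i in range(code.k - 1, -1, -1):
        out.append(_DECODE[(code.value >> (2 * i)) & 3])
    return "".join(out)


def _revcomp_value(value: int, k: int) -> int:
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | ((value & 3) ^ 3)
        value >>= 2
    return rc


def revcomp(code: KmerCode) -> KmerCode:
    """Reverse complement; an involution on the packed value."""
    return KmerCode(
        value=_revcomp_value(code.value, code.k),
        k=code.k,
        strand=REVERSE if code.strand == FORWARD else FORWARD,
        palindromic=code.palindromic,
    )


def canonical(code: Union[KmerCode, str]) -> KmerCode:
    """Return the numerically smaller of a code and its reverse complement.

    ``strand`` records which orientation won; a word equal to its own
    reverse complement is flagged ``palindromic`` (strand kept forward).
    """
    if isinstance(code, str):
        code = pack_kmer(code)
    rc = _revcomp_value(code.value, code.k)
    if rc < code.value:
        return KmerCode(value=rc, k=code.k, strand=REVERSE)
    if rc == code.value:
        return KmerCode(value=code.value, k=code.k, strand=FORWARD, palindromic=True)
    return KmerCode(value=code.value, k=code.k, strand=FORWARD)


@dataclass(frozen=True)
class SimHashConfig:
    """Width and seed of the hashing stage.

    ``b`` is the number of bits both in item hashes and in the output hash
    (1..64, default 64); ``hash_seed`` seeds the base hash.
    """

    b: int = 64
    hash_seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.b <= 64:
            raise ValueError(f"bit width b must be in [1, 64], got {self.b}")

    @property
    def mask(self) -> int:
        return (1 << self.b) - 1

    @property
    def _tweak(self) -> int:
        return (self.hash_seed * _GOLDEN) & _MASK64


def _mix64(z: int) -> int:
    """splitmix64 finalizer: an invertible avalanche mix on 64-bit words."""
    z &= _MASK64
    z ^= z >> 30
    z = (z * 0xBF58476D1CE4E5B9) & _MASK64
    z ^= z >> 27
    z = (z * 0x94D049BB133111EB) & _MASK64
    z ^= z >> 31
    return z


def base_hash(code: Union[KmerCode, int], cfg: SimHashConfig) -> int:
    """Seedable low-collision hash of a k-mer code, truncated to b bits.

    For fixed ``hash_seed`` the pre-truncation map is a bijection on
    64-bit integers, so at b=64 distinct codes never collide.
    """
    value = code.value if isinstance(code, KmerCode) else int(code)
    return _mix64(value ^ cfg._tweak) & cfg.mask


def base_hash_vec(values: np.ndarray, cfg: SimHashConfig) -> np.ndarray:
    """Vectorized :func:`base_hash` over an array of packed codes."""
    z = values.astype(np.uint64, copy=True)
    z ^= np.uint64(cfg._tweak)
    z ^= z >> np.uint64(30)
    z *= np.uint64(0xBF58476D1CE4E5B9)
    z ^= z >> np.uint64(27)
    z *= np.uint64(0x94D049BB133111EB)
    z ^= z >> np.uint64(31)
    z &= np.uint64(cfg.mask)
    return z


# 2-bit-group reversal masks for the vectorized reverse complement.
_C2 = np.uint64(0x3333333333333333)
_C4 = np.uint64(0x0F0F0F0F0F0F0F0F)


def revcomp_vec(values: np.ndarray, k: int) -> np.ndarray:
    """Vectorized reverse complement of 2-bit-packed k-mer codes."""
    x = values.astype(np.uint64, copy=True)
    x = ((x >> np.uint64(2)) & _C2) | ((x & _C2) << np.uint64(2))
    x = ((x >> np.uint64(4)) & _C4) | ((x & _C4) << np.uint64(4))
    x = x.byteswap()
    x >>= np.uint64(64 - 2 * k)
    x ^= np.uint64((1 << (2 * k)) - 1)  # complement each base (0<->3, 1<->2)
    return x


def counter_vector(items: Iterable[int], cfg: SimHashConfig) -> list[int]:
    """Encode items as +/-1 vectors and sum them (the SimHash counter vector)."""
    items = list(items)
    if not items:
        raise EmptySetError("empty set")
    counts = [0] * cfg.b
    for item in items:
        if item < 0 or item > cfg.mask:
            raise ItemOverflowError(f"item {item} exceeds {cfg.b}-bit width")
        for t in range(cfg.b):
            counts[t] += 1 if (item >> t) & 1 else -1
    return counts


def decode_counter(counts: Sequence[int]) -> int:
    """Majority-decode a counter vector: bit t = 1 iff counts[t] > 0."""
    value = 0
    for t, c in enumerate(counts):
        if c > 0:
            value |= 1 << t
    return value


def simhash(items: Iterable[int], cfg: SimHashConfig) -> int:
    """SimHash value of a multiset of b-bit item hashes.

    Per-bit majority over the items, counting multiplicity; ties (possible
    only for even multiset sizes) decode to 0.  Item order is irrelevant.
    """
    return decode_counter(counter_vector(items, cfg))


def simhash_rows(item_matrix: np.ndarray, cfg: SimHashConfig) -> np.ndarray:
    """SimHash of each row of an (m, n_items) uint64 matrix. Returns (m,) uint64."""
    if item_matrix.size == 0:
        return np.zeros(item_matrix.shape[0], dtype=np.uint64)
    shifts = np.arange(cfg.b, dtype=np.uint64)
    bits = ((item_matrix[:, :, None] >> shifts) & np.uint64(1)).astype(np.int16)
    counts = (2 * bits - 1).sum(axis=1)
    out_bits = (counts > 0).astype(np.uint64)
    return (out_bits << shifts).sum(axis=1).astype(np.uint64)


def simhash_windows(item_hashes: np.ndarray, n: int, cfg: SimHashConfig) -> np.ndarray:
    """SimHash of every window of n consecutive item hashes.

    For an input of length M returns an array of length M - n + 1 where
    entry i is the SimHash of items i .. i+n-1.  Used by the seeding layer,
    where the items of the seed starting at position i are the hashes of n
    consecutive constituent k-mers.
    """
    m = len(item_hashes) - n + 1
    if m <= 0:
        return np.zeros(0, dtype=np.uint64)
    shifts = np.arange(cfg.b, dtype=np.uint64)
    bits = ((item_hashes[:, None] >> shifts) & np.uint64(1)).astype(np.int32)
    votes = 2 * bits - 1
    csum = np.vstack([np.zeros((1, cfg.b), dtype=np.int64), votes.cumsum(axis=0)])
    counts = csum[n:] - csum[:-n]
    out_bits = (counts > 0).astype(np.uint64)
    return (out_bits << shifts).sum(axis=1).astype(np.uint64)
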