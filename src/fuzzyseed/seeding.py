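"""Seed extraction: minimizer sampling, strobemer-style linking, set conversion.

Three modes produce :class:`Seed` objects from a sequence:

* ``blend_i``  -- minimizer selection over words of length L where the
  selection value of each L-mer is its SimHash over the base hashes of its
  n overlapping sub-k-mers of length k' = L - n + 1, read on the canonical
  orientation of the L-mer.  The winning L-mer becomes a seed whose hash is
  that SimHash value, so a substitution that touches only a few sub-k-mers
  usually leaves the hash unchanged.
* ``blend_s``  -- minimizers of length k are computed first; every run of n
  consecutive minimizers sharing the orientation of the run's first
  minimizer is linked into one seed whose items are the n minimizer hashes.
  Whole strobes may mismatch between two sequences without changing the
  majority vote, which tolerates indels in the gaps.
* ``baseline`` -- plain minimizers of length L hashed with the low-collision
  base hash (the exact-match scheme fuzzy hashing is compared against).

Minimizer ties within a window select the leftmost occurrence; palindromic
words (even k only) and words containing ambiguous bases are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from fuzzyseed.core_hashing import (
    FORWARD,
    REVERSE,
    KmerCode,
    SimHashConfig,
    base_hash,
    base_hash_vec,
    revcomp_vec,
    simhash_rows,
    simhash_windows,
)

MODES = ("blend_i", "blend_s", "baseline")

_SENTINEL = np.uint64(0xFFFFFFFFFFFFFFFF)


class NeighborCountError(ValueError):
    """neighbor count too large for seed length (sub-k-mer would be < 4 bp)."""


class UnknownModeError(ValueError):
    pass


@dataclass(frozen=True)
class SeedingParams:
    """Seeding configuration.

    mode       one of ``blend_i``, ``blend_s``, ``baseline``
    seed_len   L, bases covered by a blend_i/baseline seed
    k          length of each linked k-mer (blend_s)
    window     w, number of consecutive words per minimizer window
    neighbors  n, number of set items per seed
    """

    mode: str = "blend_i"
    seed_len: int = 15
    k: int = 19
    window: int = 10
    neighbors: int = 5

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise UnknownModeError(f"unknown seeding mode {self.mode!r}")
        if self.window < 1:
            raise ValueError("window w must be >= 1")
        if self.mode == "blend_i":
            if self.neighbors < 1:
                raise ValueError("blend_i requires n >= 1")
            if self.sub_k < 4:
                raise NeighborCountError(
                    "neighbor count too large for seed length: "
                    f"L={self.seed_len}, n={self.neighbors} gives sub-k-mer "
                    f"length {self.sub_k} < 4"
                )
        if self.mode == "blend_s" and self.neighbors < 2:
            raise ValueError("blend_s requires n >= 2 linked k-mers")

    @property
    def sub_k(self) -> int:
        """Sub-k-mer length k' = L - n + 1 used by blend_i."""
        return self.seed_len - self.neighbors + 1

    @staticmethod
    def erroneous_read_defaults() -> "SeedingParams":
        """Defaults tuned for error-prone long reads (short seeds, small window)."""
        return SeedingParams(mode="blend_i", seed_len=15, neighbors=5, window=10)

    @staticmethod
    def accurate_read_defaults() -> "SeedingParams":
        """Defaults tuned for highly accurate long reads (linked k-mers, wide window)."""
        return SeedingParams(mode="blend_s", k=19, neighbors=5, window=50)


@dataclass(frozen=True)
class Seed:
    """A located span with its final hash value."""

    seq_id: str
    start: int
    span: int
    strand: str
    hash: int


_BASE_TABLE = np.full(256, -1, dtype=np.int8)
for _ch, _code in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
    _BASE_TABLE[ord(_ch)] = _code
    _BASE_TABLE[ord(_ch.lower())] = _code


def encode_bases(seq: str) -> np.ndarray:
    """Per-base 2-bit codes as int8; -1 marks ambiguous bases."""
    raw = np.frombuffer(seq.encode("latin-1"), dtype=np.uint8)
    return _BASE_TABLE[raw]


def kmer_codes(bases: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed codes for every k-mer start plus a validity mask.

    Positions whose window contains an ambiguous base are marked invalid
    (their code value is meaningless).
    """
    m = len(bases) - k + 1
    if m <= 0:
        return np.zeros(0, dtype=np.uint64), np.zeros(0, dtype=bool)
    clean = np.where(bases < 0, 0, bases).astype(np.uint64)
    codes = np.zeros(m, dtype=np.uint64)
    for i in range(k):
        codes = (codes << np.uint64(2)) | clean[i:i + m]
    bad = np.concatenate([[0], np.cumsum((bases < 0).astype(np.int64))])
    valid = (bad[k:] - bad[:-k]) == 0
    return codes, valid


def _select_minimizers(values: np.ndarray, valid: np.ndarray, w: int) -> np.ndarray:
    """Leftmost-argmin minimizer positions over windows of w values.

    Consecutive windows selecting the same position emit it once; invalid
    positions never win unless a window contains no valid value, in which
    case that window emits nothing.
    """
    m = len(values)
    if m == 0:
        return np.zeros(0, dtype=np.int64)
    sel = np.where(valid, values, _SENTINEL)
    weff = min(w, m)
    windows = sliding_window_view(sel, weff)
    picks = windows.argmin(axis=1) + np.arange(len(windows))
    picks = np.unique(picks)  # a position wins only in consecutive windows
    return picks[valid[picks]]


def minimizers(
    seq: str,
    k: int,
    w: int,
    hasher: Optional[Callable[[KmerCode], int]] = None,
    cfg: Optional[SimHashConfig] = None,
    canonicalize: bool = True,
) -> list[tuple[int, KmerCode, str, int]]:
    """Minimizer k-mers of a sequence.

    Every window of w consecutive k-mer hash values contributes the k-mer
    with the minimum value (leftmost on ties).  Returns a position-sorted
    list of ``(position, code, strand, hash)``.  By default k-mers are
    canonicalized and hashed with the seedable base hash; a custom
    ``hasher`` (mapping a :class:`KmerCode` to an integer) and
    ``canonicalize=False`` support controlled experiments.
    """
    if hasher is None:
        if cfg is None:
            cfg = SimHashConfig()
        hasher = lambda code: base_hash(code, cfg)  # noqa: E731

    bases = encode_bases(seq)
    fwd, valid = kmer_codes(bases, k)
    if len(fwd) == 0:
        return []
    if canonicalize:
        rc = revcomp_vec(fwd, k)
        canon = np.minimum(fwd, rc)
        strands = np.where(rc < fwd, REVERSE, FORWARD)
        valid = valid & (fwd != rc)  # palindromes are skipped
    else:
        canon = fwd
        strands = np.full(len(fwd), FORWARD)

    values = np.array(
        [hasher(KmerCode(int(v), k, str(s))) if ok else 0
         for v, s, ok in zip(canon, strands, valid)],
        dtype=np.uint64,
    )
    picks = _select_minimizers(values, valid, w)
    return [
        (int(i), KmerCode(int(canon[i]), k, str(strands[i])), str(strands[i]), int(values[i]))
        for i in picks
    ]


def _minimizer_arrays(
    bases: np.ndarray, k: int, w: int, cfg: SimHashConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized canonical minimizers: (positions, strand_is_rev, hashes)."""
    fwd, valid = kmer_codes(bases, k)
    if len(fwd) == 0:
        empty = np.zeros(0, dtype=np.int64)
        return empty, np.zeros(0, dtype=bool), np.zeros(0, dtype=np.uint64)
    rc = revcomp_vec(fwd, k)
    canon = np.minimum(fwd, rc)
    is_rev = rc < fwd
    valid = valid & (fwd != rc)
    hashes = base_hash_vec(canon, cfg)
    picks = _select_minimizers(hashes, valid, w)
    return picks, is_rev[picks], hashes[picks]


def blend_i_seeds(
    seq: str, params: SeedingParams, cfg: SimHashConfig, seq_id: str = "seq"
) -> list[Seed]:
    """Fuzzy-hashed minimizer seeds (substitution-sensitive conversion).

    The selection value of each L-mer *is* its SimHash, so the window
    minimum is taken over fuzzy hash values and two sequences sharing a
    similar L-mer tend to select and hash it identically.
    """
    if params.mode != "blend_i":
        raise UnknownModeError("params.mode must be 'blend_i'")
    L, n, kp = params.seed_len, params.neighbors, params.sub_k
    bases = encode_bases(seq)
    sub_fwd, _ = kmer_codes(bases, kp)
    if len(sub_fwd) < n:
        return []
    sub_rc = revcomp_vec(sub_fwd, kp)
    # Items of the L-mer at i, read on its canonical orientation: the n
    # sub-k-mers of the canonical text.  For a reverse-canonical L-mer the
    # item multiset equals the reverse complements of the forward sub-k-mers.
    hf = simhash_windows(base_hash_vec(sub_fwd, cfg), n, cfg)
    hr = simhash_windows(base_hash_vec(sub_rc, cfg), n, cfg)

    lmer_fwd, valid = kmer_codes(bases, L)
    lmer_rc = revcomp_vec(lmer_fwd, L)
    is_rev = lmer_rc < lmer_fwd
    valid = valid & (lmer_fwd != lmer_rc)
    values = np.where(is_rev, hr, hf)

    picks = _select_minimizers(values, valid, params.window)
    return [
        Seed(seq_id, int(i), L, REVERSE if is_rev[i] else FORWARD, int(values[i]))
        for i in picks
    ]


def blend_s_seeds(
    seq: str, params: SeedingParams, cfg: SimHashConfig, seq_id: str = "seq"
) -> list[Seed]:
    """Strobemer-style linked seeds (indel-tolerant conversion).

    Runs of n consecutive minimizers whose orientations all match the run's
    first minimizer are linked into one seed; mixed-orientation runs are
    skipped entirely so every seed votes with exactly n items.
    """
    if params.mode != "blend_s":
        raise UnknownModeError("params.mode must be 'blend_s'")
    n = params.neighbors
    bases = encode_bases(seq)
    pos, is_rev, hashes = _minimizer_arrays(bases, params.k, params.window, cfg)
    m = len(pos)
    if m < n:
        return []
    runs = sliding_window_view(hashes, n)
    run_rev = sliding_window_view(is_rev, n)
    same_strand = (run_rev == run_rev[:, :1]).all(axis=1)
    values = simhash_rows(runs.astype(np.uint64), cfg)
    seeds = []
    for i in range(m - n + 1):
        if not same_strand[i]:
            continue
        start = int(pos[i])
        span = int(pos[i + n - 1]) + params.k - start
        strand = REVERSE if is_rev[i] else FORWARD
        seeds.append(Seed(seq_id, start, span, strand, int(values[i])))
    return seeds


def baseline_seeds(
    seq: str, params: SeedingParams, cfg: SimHashConfig, seq_id: str = "seq"
) -> list[Seed]:
    """Plain minimizer seeds hashed with the low-collision base hash."""
    bases = encode_bases(seq)
    L = params.seed_len
    pos, is_rev, hashes = _minimizer_arrays(bases, L, params.window, cfg)
    return [
        Seed(seq_id, int(p), L, REVERSE if r else FORWARD, int(h))
        for p, r, h in zip(pos, is_rev, hashes)
    ]


def seed_stream(
    seq: Union[str, "object"],
    params: SeedingParams,
    cfg: SimHashConfig,
    seq_id: Optional[str] = None,
) -> list[Seed]:
    """Dispatch to the configured seeding mode; output sorted by start.

    ``seq`` may be a plain string or any object with ``.seq`` and ``.name``
    attributes (e.g. :class:`fuzzyseed.formats.SeqRecord`).
    """
    if hasattr(seq, "seq"):
        if seq_id is None:
            seq_id = getattr(seq, "name", "seq")
        seq = seq.seq
    if seq_id is None:
        seq_id = "seq"
    if params.mode == "blend_i":
        return blend_i_seeds(seq, params, cfg, seq_id)
    if params.mode == "blend_s":
        return blend_s_seeds(seq, params, cfg, seq_id)
    if params.mode == "baseline":
        return baseline_seeds(seq, params, cfg, seq_id)
    raise UnknownModeError(f"unknown seeding mode {params.mode!r}")


def hash_single_word(word: str, params: SeedingParams, cfg: SimHashConfig) -> int:
    """Hash one word of length L directly, without minimizer selection.

    In blend_i mode this is the SimHash of the base hashes of the word's n
    overlapping sub-k-mers; in baseline mode, the base hash of the packed
    word.  The forward orientation is hashed as given (no canonicalization),
    which isolates the hash mechanism itself in calibration experiments.
    """
    bases = encode_bases(word)
    if (bases < 0).any():
        raise AmbiguousWordError(word)
    if params.mode == "baseline":
        codes, _ = kmer_codes(bases, len(word))
        return int(base_hash_vec(codes, cfg)[0])
    if params.mode == "blend_i":
        if len(word) != params.seed_len:
            raise ValueError("word length must equal params.seed_len")
        codes, _ = kmer_codes(bases, params.sub_k)
        items = base_hash_vec(codes, cfg)
        return int(simhash_windows(items, params.neighbors, cfg)[0])
    raise UnknownModeError(f"hash_single_word does not support mode {params.mode!r}")


class AmbiguousWordError(ValueError):
    pass
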