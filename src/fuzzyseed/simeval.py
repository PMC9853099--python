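"""Synthetic data generation and empirical analysis of fuzzy seed matching.

This module provides everything needed to exercise the hashing, seeding,
indexing and chaining layers end-to-end without external datasets:

* random and tandem-repeat genome constructors, a per-base mutation model
  with a recorded truth list, and a read simulator with truth intervals;
* an edit-distance oracle (edlib, unit-cost Levenshtein);
* collision histograms -- edit distance between non-identical seeds that
  share a hash value, the diagnostic separating fuzzy from low-collision
  hashing;
* the fuzzy-uplift experiment -- the fraction of (word, 1-substitution
  mutant) pairs that keep the same hash, per scheme;
* overlap recall/precision of a PAF output against simulator truth.

Every experiment is reproducible bit-exactly from (inputs, rng_seed,
params).
"""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import edlib
import numpy as np

from fuzzyseed.core_hashing import SimHashConfig
from fuzzyseed.formats import SeqRecord, reverse_complement
from fuzzyseed.seeding import SeedingParams, seed_stream

_BASES = "ACGT"


@dataclass(frozen=True)
class MutationProfile:
    """Per-base substitution / insertion / deletion probabilities."""

    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sub_rate, self.ins_rate, self.del_rate) < 0:
            raise ValueError("mutation rates must be >= 0")
        if self.sub_rate + self.ins_rate + self.del_rate > 1:
            raise ValueError("sub_rate + ins_rate + del_rate must not exceed 1")


def random_genome(
    length: int, gc_fraction: float = 0.5, rng_seed: int = 0, name: str = "genome"
) -> SeqRecord:
    """I.i.d. random genome with P(G) + P(C) = gc_fraction, split evenly."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    p_at = (1 - gc_fraction) / 2
    p_gc = gc_fraction / 2
    codes = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    return SeqRecord(name=name, seq="".join(_BASES[c] for c in codes))


def make_tandem_genome(
    unit_length: int = 500,
    copies: int = 200,
    subs_per_copy: int = 1,
    gc_fraction: float = 0.5,
    rng_seed: int = 0,
    name: str = "tandem",
) -> SeqRecord:
    """Tandem copies of one random unit, each carrying a few substitutions.

    The construction guarantees that highly similar (but non-identical)
    seeds recur across copies, which makes hash collisions between similar
    seeds reachable on a small synthetic genome -- the collision stress
    test that an i.i.d. genome cannot provide.
    """
    rng = np.random.default_rng(rng_seed)
    unit = random_genome(unit_length, gc_fraction, rng_seed=int(rng.integers(2**31)))
    parts = []
    for _ in range(copies):
        copy = list(unit.seq)
        positions = rng.choice(unit_length, size=min(subs_per_copy, unit_length), replace=False)
        for p in positions:
            old = copy[p]
            copy[p] = _BASES[(_BASES.index(old) + int(rng.integers(1, 4))) % 4]
        parts.append("".join(copy))
    return SeqRecord(name=name, seq="".join(parts))


def mutate(seq: str, profile: MutationProfile) -> Tuple[str, List[Tuple[str, int, str]]]:
    """Apply the mutation model position by position.

    Per original position: an insertion of one random base before it with
    probability ``ins_rate``; then a deletion with probability ``del_rate``
    or a substitution to a uniformly different base with probability
    ``sub_rate``.  Returns the mutated sequence and the truth list of
    ``(op, original position, base)`` edits.
    """
    rng = np.random.default_rng(profile.rng_seed)
    n = len(seq)
    u_ins = rng.random(n)
    u_event = rng.random(n)
    ins_base = rng.integers(0, 4, size=n)
    sub_shift = rng.integers(1, 4, size=n)
    out: List[str] = []
    ops: List[Tuple[str, int, str]] = []
    for i, ch in enumerate(seq):
        if u_ins[i] < profile.ins_rate:
            b = _BASES[ins_base[i]]
            out.append(b)
            ops.append(("ins", i, b))
        if u_event[i] < profile.del_rate:
            ops.append(("del", i, ch))
            continue
        if u_event[i] < profile.del_rate + profile.sub_rate:
            code = "ACGT".find(ch.upper())
            if code < 0:
                out.append(ch)
                continue
            b = _BASES[(code + sub_shift[i]) % 4]
            out.append(b)
            ops.append(("sub", i, b))
        else:
            out.append(ch)
    return "".join(out), ops


@dataclass(frozen=True)
class TruthInterval:
    """Where a simulated read truly came from (0-based, half-open)."""

    seq_id: str
    start: int
    end: int
    strand: str


def simulate_reads(
    genome: SeqRecord,
    coverage: float,
    read_len_mean: int = 2000,
    read_len_sd: float = 0.0,
    profile: MutationProfile = MutationProfile(),
) -> Tuple[List[SeqRecord], Dict[str, TruthInterval]]:
    """Simulate reads with uniform starts, truncated-normal lengths, both strands.

    Each read is extracted from the genome, reverse-complemented for '-'
    strand reads, then passed through :func:`mutate` with a read-specific
    seed derived from ``profile.rng_seed``.  Returns FASTQ-style records
    (constant quality) and per-read truth intervals.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    g = len(genome.seq)
    rng = np.random.default_rng(profile.rng_seed)
    n_reads = max(1, int(round(coverage * g / read_len_mean)))
    reads: List[SeqRecord] = []
    truth: Dict[str, TruthInterval] = {}
    for i in range(n_reads):
        length = int(round(rng.normal(read_len_mean, read_len_sd))) if read_len_sd > 0 else read_len_mean
        length = max(100, min(length, g))
        start = int(rng.integers(0, g - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        fragment = genome.seq[start:start + length]
        if strand == "-":
            fragment = reverse_complement(fragment)
        read_profile = MutationProfile(
            sub_rate=profile.sub_rate,
            ins_rate=profile.ins_rate,
            del_rate=profile.del_rate,
            rng_seed=int(rng.integers(2**31)),
        )
        mutated, _ = mutate(fragment, read_profile)
        name = f"read{i:05d}"
        reads.append(SeqRecord(name=name, seq=mutated, qual="I" * len(mutated)))
        truth[name] = TruthInterval(genome.name, start, start + length, strand)
    return reads, truth


def edit_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance (edlib NW)."""
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


@dataclass
class CollisionHistogram:
    """Non-identical colliding seed pairs tallied by edit distance."""

    counts: Dict[int, int] = field(default_factory=dict)
    subsampled: bool = False
    pairs_evaluated: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def ratios(self) -> Dict[int, float]:
        total = self.total
        if total == 0:
            return {}
        return {d: c / total for d, c in sorted(self.counts.items())}

    def mass_at_most(self, d_max: int) -> float:
        return sum(r for d, r in self.ratios.items() if d <= d_max)

    def count_above(self, d_min: int) -> int:
        return sum(c for d, c in self.counts.items() if d > d_min)


def collision_histogram(
    seq: SeqRecord,
    params: SeedingParams,
    cfg: SimHashConfig,
    max_pairs: int = 200_000,
    rng_seed: int = 0,
) -> CollisionHistogram:
    """Edit-distance histogram over non-identical seed pairs sharing a hash.

    All seeds of ``seq`` are grouped by hash value; within each group every
    pair of seeds whose underlying (orientation-adjusted) subsequences
    differ contributes its edit distance, weighted by how often that text
    pair occurs.  If the number of distinct text pairs exceeds
    ``max_pairs`` a seeded uniform subsample is evaluated and flagged.
    """
    text = seq.seq
    groups: Dict[int, Counter] = defaultdict(Counter)
    for seed in seed_stream(seq, params, cfg):
        sub = text[seed.start:seed.start + seed.span]
        if seed.strand == "-":
            sub = reverse_complement(sub)
        groups[seed.hash][sub] += 1

    pair_jobs: List[Tuple[str, str, int]] = []
    for counter in groups.values():
        if len(counter) < 2:
            continue
        texts = sorted(counter)
        for a, b in itertools.combinations(texts, 2):
            pair_jobs.append((a, b, counter[a] * counter[b]))

    hist = CollisionHistogram()
    if len(pair_jobs) > max_pairs:
        rng = np.random.default_rng(rng_seed)
        chosen = rng.choice(len(pair_jobs), size=max_pairs, replace=False)
        pair_jobs = [pair_jobs[i] for i in sorted(chosen)]
        hist.subsampled = True
    for a, b, weight in pair_jobs:
        d = edit_distance(a, b)
        hist.counts[d] = hist.counts.get(d, 0) + weight
        hist.pairs_evaluated += 1
    return hist


def uplift_experiment(
    num_pairs: int,
    L: int,
    d: int,
    params_blend: SeedingParams,
    params_baseline: SeedingParams,
    cfg: SimHashConfig,
    rng_seed: int = 0,
    cfg_baseline: Optional[SimHashConfig] = None,
) -> Tuple[float, float]:
    """Same-hash rate of (word, d-substitution mutant) pairs per scheme.

    ``num_pairs`` random L-mers are each mutated by exactly ``d``
    substitutions at distinct random positions; both members are hashed
    under the fuzzy scheme and under the baseline hash, and the fraction of
    pairs with equal hashes is returned as ``(blend_rate, baseline_rate)``.
    ``d = 0`` is allowed for calibration (both rates are then 1 by
    determinism).  Words are hashed in their forward orientation to isolate
    the hash mechanism from strand handling.
    """
    if d >= L:
        raise ValueError("invalid distance: d must be < L")
    if cfg_baseline is None:
        cfg_baseline = cfg
    rng = np.random.default_rng(rng_seed)
    words = rng.integers(0, 4, size=(num_pairs, L), dtype=np.int8)
    mutants = words.copy()
    if d > 0:
        pos = np.argsort(rng.random((num_pairs, L)), axis=1)[:, :d]
        rows = np.arange(num_pairs)[:, None]
        shift = rng.integers(1, 4, size=(num_pairs, d)).astype(np.int8)
        mutants[rows, pos] = (mutants[rows, pos] + shift) % 4

    def _hash_all(mat: np.ndarray, params: SeedingParams, c: SimHashConfig) -> np.ndarray:
        from fuzzyseed.core_hashing import base_hash_vec, simhash_rows

        if params.mode == "baseline":
            codes = np.zeros(mat.shape[0], dtype=np.uint64)
            for col in range(L):
                codes = (codes << np.uint64(2)) | mat[:, col].astype(np.uint64)
            return base_hash_vec(codes, c)
        if params.mode == "blend_i":
            kp = params.sub_k
            n = params.neighbors
            items = np.zeros((mat.shape[0], n), dtype=np.uint64)
            for j in range(n):
                code = np.zeros(mat.shape[0], dtype=np.uint64)
                for col in range(j, j + kp):
                    code = (code << np.uint64(2)) | mat[:, col].astype(np.uint64)
                items[:, j] = base_hash_vec(code, c)
            return simhash_rows(items, c)
        raise ValueError(f"unsupported mode {params.mode!r} in uplift experiment")

    blend_equal = _hash_all(words, params_blend, cfg) == _hash_all(mutants, params_blend, cfg)
    base_equal = (
        _hash_all(words, params_baseline, cfg_baseline)
        == _hash_all(mutants, params_baseline, cfg_baseline)
    )
    return float(blend_equal.mean()), float(base_equal.mean())


@dataclass(frozen=True)
class OverlapStats:
    recall: float
    precision: float
    n_true_pairs: int
    n_reported_pairs: int
    nothing_reported: bool = False


def true_overlap_pairs(
    truth: Dict[str, TruthInterval], min_true_overlap: int = 500
) -> set:
    """Unordered read pairs whose truth intervals intersect by >= the cutoff."""
    names = sorted(truth)
    pairs = set()
    for i, a in enumerate(names):
        ta = truth[a]
        for b in names[i + 1:]:
            tb = truth[b]
            if ta.seq_id != tb.seq_id:
                continue
            overlap = min(ta.end, tb.end) - max(ta.start, tb.start)
            if overlap >= min_true_overlap:
                pairs.add(frozenset((a, b)))
    return pairs


def overlap_recall(
    truth: Dict[str, TruthInterval],
    paf_records: Iterable,
    min_true_overlap: int = 500,
) -> OverlapStats:
    """Recall and precision of reported overlap pairs against simulator truth.

    A reported pair is any (query, target) with distinct names appearing in
    the PAF output.  When nothing is reported, recall is 0 and precision is
    reported as 0 with ``nothing_reported`` set.
    """
    true_pairs = true_overlap_pairs(truth, min_true_overlap)
    reported = set()
    for rec in paf_records:
        if rec.query_name != rec.target_name:
            reported.add(frozenset((rec.query_name, rec.target_name)))
    found = reported & true_pairs
    recall = len(found) / len(true_pairs) if true_pairs else 0.0
    if not reported:
        return OverlapStats(recall, 0.0, len(true_pairs), 0, nothing_reported=True)
    return OverlapStats(recall, len(found) / len(reported), len(true_pairs), len(reported))


# ---------------------------------------------------------------------------
# Chaining oracle: exhaustive search over co-linear subsets (small instances).

def exhaustive_best_chain_score(anchors: Sequence, max_gap: int) -> int:
    """Optimal chain score by enumerating every subset of <= ~12 anchors.

    Independent of the DP: a subset is a valid chain when, sorted by query
    start, consecutive members strictly increase in (q, oriented t) with
    both deltas within ``max_gap``; its score is the span sum minus the
    diagonal-drift costs.  Returns the maximum over all non-empty subsets.
    """
    m = len(anchors)
    if m == 0:
        return 0
    opposite = anchors[0].strand_pair == "opposite"
    coords = [
        (a.q_start, -a.t_start if opposite else a.t_start, a.span) for a in anchors
    ]
    best = 0
    for mask in range(1, 1 << m):
        subset = [coords[i] for i in range(m) if mask & (1 << i)]
        subset.sort()
        score = subset[0][2]
        valid = True
        for (q0, t0, _), (q1, t1, s1) in zip(subset, subset[1:]):
            dq, dt = q1 - q0, t1 - t0
            if dq <= 0 or dt <= 0 or dq > max_gap or dt > max_gap:
                valid = False
                break
            score += s1 - abs(dq - dt)
        if valid and score > best:
            best = score
    return best


# ---------------------------------------------------------------------------
# End-to-end experiment drivers reused by the test suite and by
# scripts/acceptance.py.  Problem sizes are desk-scale by design: a 100 kb
# random genome resolves 15-mers almost uniquely, and a few hundred reads
# are enough to measure completeness and recall with no sampling noise of
# consequence.

def mapping_completeness(
    params: SeedingParams,
    cfg: SimHashConfig,
    genome_length: int = 100_000,
    n_reads: int = 200,
    read_len: int = 2000,
    rng_seed: int = 0,
    min_coverage: float = 0.99,
    locus_slop: int = 200,
):
    """Map error-free simulated reads back to their genome.

    Returns the fraction of reads for which some reported chain covers at
    least ``min_coverage`` of the read, lies at the true locus (target
    interval within the truth interval widened by ``locus_slop``) and on
    the true strand.
    """
    from fuzzyseed.indexing import build_index, filter_frequent
    from fuzzyseed.pipeline import ChainingOptions, map_queries

    genome = random_genome(genome_length, rng_seed=rng_seed)
    profile = MutationProfile(rng_seed=rng_seed + 1)
    coverage = n_reads * read_len / genome_length
    reads, truth = simulate_reads(genome, coverage, read_len, 0.0, profile)
    reads = reads[:n_reads]
    index = filter_frequent(build_index([genome], params, cfg))
    complete = 0
    for rec in map_queries(index, reads, ChainingOptions()):
        t = truth[rec.query_name]
        if rec.strand != t.strand:
            continue
        if rec.query_end - rec.query_start < min_coverage * rec.query_len:
            continue
        if rec.target_start < t.start - locus_slop or rec.target_end > t.end + locus_slop:
            continue
        complete += 1
        truth.pop(rec.query_name, None)  # count each read once
    return complete / n_reads


def collision_skew_experiment(
    cfg: SimHashConfig = SimHashConfig(b=16),
    seed_len: int = 15,
    neighbors: int = 5,
    window: int = 10,
    genome_length: int = 100_000,
    unit_length: int = 500,
    subs_per_copy: int = 16,
    rng_seed: int = 0,
    max_pairs: int = 100_000,
) -> Tuple[CollisionHistogram, CollisionHistogram]:
    """Collision histograms of the fuzzy and baseline schemes side by side.

    Runs both schemes over the same tandem-mutated genome, where
    near-identical seeds recur by construction (copy divergence
    ``subs_per_copy / unit_length``, ~3% at the defaults), and returns
    ``(fuzzy histogram, baseline histogram)``.  The default 16-bit hash
    width keeps both the similar-seed collisions and the random background
    collisions at measurable counts on a 100 kb genome.
    """
    copies = genome_length // unit_length
    genome = make_tandem_genome(
        unit_length=unit_length, copies=copies, subs_per_copy=subs_per_copy,
        rng_seed=rng_seed,
    )
    blend = SeedingParams(mode="blend_i", seed_len=seed_len,
                          neighbors=neighbors, window=window)
    base = SeedingParams(mode="baseline", seed_len=seed_len,
                         neighbors=neighbors, window=window)
    h_blend = collision_histogram(genome, blend, cfg, max_pairs=max_pairs, rng_seed=rng_seed)
    h_base = collision_histogram(genome, base, cfg, max_pairs=max_pairs, rng_seed=rng_seed)
    return h_blend, h_base


def overlap_recall_experiment(
    params: SeedingParams,
    cfg: SimHashConfig,
    genome_length: int = 50_000,
    coverage: float = 20.0,
    read_len: int = 2000,
    sub_rate: float = 0.05,
    ins_rate: float = 0.01,
    del_rate: float = 0.01,
    min_true_overlap: int = 500,
    rng_seed: int = 0,
) -> OverlapStats:
    """All-vs-all overlap detection on simulated erroneous reads vs truth."""
    from fuzzyseed.pipeline import overlap_reads

    genome = random_genome(genome_length, rng_seed=rng_seed)
    profile = MutationProfile(sub_rate=sub_rate, ins_rate=ins_rate,
                              del_rate=del_rate, rng_seed=rng_seed + 1)
    reads, truth = simulate_reads(genome, coverage, read_len, 0.0, profile)
    records = overlap_reads(reads, params, cfg)
    return overlap_recall(truth, records, min_true_overlap)


def random_anchor_instance(rng: np.random.Generator, max_anchors: int = 12):
    """A small random anchor set for oracle-vs-DP chaining comparisons."""
    from fuzzyseed.chaining import Anchor

    m = int(rng.integers(1, max_anchors + 1))
    strand = "same" if rng.random() < 0.5 else "opposite"
    anchors = [
        Anchor(
            target_id="t",
            q_start=int(rng.integers(0, 100)),
            t_start=int(rng.integers(0, 100)),
            span=int(rng.integers(5, 21)),
            strand_pair=strand,
        )
        for _ in range(m)
    ]
    anchors.sort(key=lambda a: (a.target_id, a.strand_pair, a.t_start, a.q_start))
    return anchors
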