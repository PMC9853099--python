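# Methods

## The problem

Seed-and-extend methods find candidate similarities between nucleotide
sequences by matching short *seeds* through a hash table: every seed of the
target set is stored under its hash value, and each query seed retrieves
its matches with a single lookup. With a conventional low-collision hash,
two seeds match only if they are textually identical, which forces short
seeds (losing specificity) or loses sensitivity on divergent or erroneous
reads. fuzzyseed assigns the *same* hash value to highly similar seeds, so
one lookup returns both exact and approximate ("fuzzy") matches.

## Hashing model

A seed is converted to a multiset of b-bit item hashes and reduced by a
SimHash-style per-bit majority vote:

1. each item hash `x` is encoded as a vector `v ∈ {−1, +1}^b` with
   `v_t = +1` iff bit `t` of `x` is 1;
2. the vectors are summed into a counter vector
   `c_t = (# items with bit t set) − (# items with bit t clear)`, counting
   multiplicity;
3. output bit `t` is 1 iff `c_t > 0`; ties (`c_t = 0`, possible only for
   even multiset sizes) decode to 0.

Replacing one of `m` items changes each counter by at most 2, so any bit
with `|c_t| > 2` is unchanged; with most bits holding a solid majority, a
seed pair differing in a few items keeps the same hash value with a
probability far above the `2^-b` of an unrelated pair. Bit `t = 0` is the
least-significant bit everywhere.

Item hashes come from a seedable splitmix64-style finalizer applied to the
2-bit-packed k-mer code (`A=0, C=1, G=2, T=3`, first base most
significant), truncated to `b` bits. For a fixed seed the 64-bit map is a
bijection, so at `b = 64` distinct k-mers never collide — this is also the
`baseline` hashing mode that the fuzzy modes are compared against.

Two sequence-to-set conversions are provided:

* **blend_i** — a seed is a word of length `L`; its items are the base
  hashes of its `n` overlapping sub-k-mers of length `k' = L − n + 1`, read
  on the canonical orientation of the word. A single substitution near a
  word end touches few sub-k-mers and often leaves the majority intact.
  Words are sampled as minimizers over windows of `w` consecutive words,
  and the *selection value is the SimHash itself*, so two sequences sharing
  a similar word tend to select and hash it identically.
* **blend_s** — canonical minimizers of length `k` are computed first; each
  run of `n` consecutive minimizers whose orientations all match the run's
  first minimizer is linked into one seed whose items are the `n` minimizer
  base hashes. A whole strobe may mismatch without changing the majority,
  and the gaps between strobes absorb indels. Mixed-orientation runs are
  skipped entirely so every seed votes with exactly `n` items.

Canonical k-mers are the numerically smaller of a code and its reverse
complement; palindromic words (possible only at even k) are skipped, and
the default word lengths are odd so none occur. Minimizer ties select the
leftmost occurrence. Repeated items are genuine multiset members (no
deduplication), matching the vector-sum formulation.

## Indexing and chaining

The index maps hash value → list of `(seq_id, start, span, strand)`
records, sorted for determinism; keys occurring more than `max_occ`
(default 1000) times are dropped as repeats. Each (query seed, same-hash
target record) pair becomes an anchor; anchors grouped by (target, strand
pairing) are chained by exact dynamic programming maximizing
`Σ span − Σ |Δq − Δt|` over strictly co-linear predecessors with both
deltas in `(0, max_gap]` (default 5000). The linear diagonal-drift cost is
deliberately simple: it admits an exhaustive-subset oracle, which the test
suite uses to verify DP optimality on a thousand random instances. Chains
are extracted best-score-first with anchor consumption; chains below
`min_chain_score` (40) or `min_anchors` (3) are discarded. Mapping quality
is `floor(40·(1 − s2/s1))` clamped to [0, 60] with `s2` the best other
chain on the same query — deterministic and monotone in score separation.
Output is 12-column PAF with `cm` (anchor count) and `s1` (chain score)
tags; coordinates are 0-based half-open, reverse-strand records report
forward-strand target coordinates.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `b` | 64 | hash width, bits (1–64); narrower widths trade specificity for collision rate |
| `hash_seed` | 0 | seed of the base hash |
| `L` (`--seed-len`) | 15 | word length, blend_i / baseline |
| `k` | 19 | linked k-mer length, blend_s |
| `w` | 10 | minimizer window (words per window); 10 suits erroneous reads, ~50 accurate long reads |
| `n` (`--neighbors`) | 5 | items per seed; larger n = smaller sub-k-mers = more fuzziness |
| `max_occ` | 1000 | repeat filter on index buckets |
| `max_gap`, `min_chain_score`, `min_anchors` | 5000, 40, 3 | chaining |

With `n = 1`, blend_i degenerates to exactly the baseline minimizer scheme
(single-item majority is the item itself).

## Synthetic data and what the experiments show

The simulator generates i.i.d. random genomes (uniform or GC-controlled),
reads with uniform starts, truncated-normal lengths, uniform strands, and
independent per-base substitutions/insertions/deletions with a recorded
truth interval per read. A tandem-repeat constructor concatenates copies of
one random unit, each copy carrying a fixed number of random substitutions.
None of this reproduces real repeat structure, error burstiness, quality
profiles, or chimeras; passing results demonstrate the mechanism's
properties (fuzzy collisions concentrate at small edit distances, fuzzy
matching does not lose exact matches, chaining is optimal under its own
cost model), not benchmark performance on real genomes.

Experiment design notes, decided once when the experiments were written:

* **Fuzzy uplift** draws random L-mers, plants exactly `d` substitutions at
  distinct positions, and compares same-hash rates. Words are hashed in
  their *forward* orientation: an end substitution can flip which
  orientation is canonical, and canonicalizing would measure strand
  handling rather than the hash. At the headline condition
  (L=15, n=5, d=1, b=32) only substitutions at the outermost word positions
  leave a 4/5 item majority, giving an expected same-hash rate of order
  1e-4 — small but strictly positive, against an exactly-zero baseline.
  Rates grow with `n` (smaller sub-k-mers localize each substitution), the
  trend the neighbor-monotonicity check asserts; at rates this small the
  trend carries seed-level noise, which is why the experiments fix their
  generators' seeds.
* **Collision histograms** group all seeds of one sequence by hash and tally
  the edit distance of every non-identical colliding text pair (weighted by
  occurrence counts; a seeded uniform subsample is taken and flagged above
  `max_pairs`). The skew experiment uses a 100 kb tandem genome
  (500 bp × 200 copies, 16 substitutions per copy ≈ 3% divergence) and a
  16-bit hash width: wide enough that buckets are meaningful, narrow enough
  that both the similar-seed collisions (edit distance ≤ 2) and the random
  background (edit distance > 6, needed as a comparison level for the
  baseline) occur in the hundreds on a desk-scale genome. At `b = 64`
  fuzzy collisions have expected counts ≪ 1 at this scale — observable
  only on chromosome-scale inputs.
* **Mapping completeness** maps 200 error-free 2 kb reads against their
  100 kb source and demands a ≥ 99%-covering chain at the true locus.
  blend_i (w=10) achieves 100%: the window guarantee bounds the unseeded
  read margins by w + L. blend_s (w=50) cannot reach this bar *by
  construction*: the first/last minimizer sits uniformly within ~50 bases
  of each read end (expected coverage ≈ 97.5%), and skipping
  mixed-orientation strobe runs keeps only ~2^-(n-1) of runs, so some reads
  have fewer seeds than `min_anchors`. This is a known, documented
  limitation of the linked-seed sampling at wide windows, not a defect of
  the hash; blend_s is aimed at overlap detection between long accurate
  reads, where full-read coverage is not the objective.
* **Overlap recall** simulates 20× coverage of 2 kb reads at 5%
  substitutions + 1%/1% indels over a 50 kb genome, runs all-vs-all overlap
  for blend_i and baseline at identical (L, w), and scores both against
  truth intervals intersecting by ≥ 500 bases.

## Numerical and degenerate-input choices

* All arithmetic on packed codes and hashes is modular uint64; vectorized
  paths (numpy) are bit-exact with the scalar definitions (tested).
* Windows shorter than `w` at a sequence end of length ≥ k are treated as a
  single window; sequences shorter than k seed nothing.
* Ambiguous bases (N etc.) invalidate every word containing them; windows
  keep their remaining valid words, and windows with none emit nothing.
* Empty multisets and items wider than `b` bits are errors, not silent
  truncation.
* The mutation model allows rate sums up to 1 so a pure-substitution
  channel (`sub_rate = 1`) is expressible.
* PAF records are validated on write and on parse (half-open non-empty
  intervals, strand, mapq ≤ 255); failed CLI runs leave no partial output.

## Problem sizes

The shipped experiments run on 100 kb genomes, 200–500 reads, 10⁴ word
pairs, and 10³ chaining instances — sizes chosen so every experiment
re-runs from scratch in seconds to a couple of minutes on one CPU while
keeping sampling noise well below the effects being measured.
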