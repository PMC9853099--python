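# fuzzyseed

Fuzzy seed matching for nucleotide sequences: a seed-hashing mechanism that
assigns the **same hash value to highly similar seeds**, so that approximate
seed matches between genomic sequences are found with a **single hash-table
lookup** — plus the minimizer/strobemer seeding, indexing, co-linear
chaining, and synthetic-data evaluation machinery to use it end to end for
read mapping and all-vs-all read overlapping.

It is aimed at people building or studying long-read overlappers and
mappers: conventional pipelines hash seeds with a low-collision function,
so seeds must match *exactly*; under sequencing error or divergence that
costs sensitivity or forces short, unspecific seeds.

## The mechanism

A seed is converted to a multiset of `b`-bit item hashes and reduced by a
per-bit majority vote (SimHash): with counter
`c_t = #{items with bit t = 1} − #{items with bit t = 0}`, output bit `t`
is 1 iff `c_t > 0` (ties → 0). Two seeds differing in a few items keep the
same hash with high probability, while unrelated seeds collide at the
usual `2^-b` rate. Two sequence-to-set conversions are provided:

* `blend_i` — items are the base hashes of all `n` overlapping sub-k-mers
  (length `k' = L − n + 1`) of an `L`-long minimizer word: sensitive to
  substitutions;
* `blend_s` — items are the base hashes of `n` linked consecutive
  same-strand minimizers (strobemer-style): tolerates indels between, and
  mismatches of, whole strobes;
* `baseline` — the plain low-collision hash (seedable invertible 64-bit
  finalizer) for side-by-side comparison.

Matches are chained per target and strand pairing by dynamic programming
(score = anchor span sum minus diagonal-drift gap costs `|Δq − Δt|`) and
reported as 12-column PAF.

## Worked example

Simulate a 50 kb genome and 2 kb reads with 5% substitutions and 1%/1%
indels, then map the reads back:

```python
from fuzzyseed.simeval import MutationProfile, random_genome, simulate_reads

genome = random_genome(50_000, rng_seed=1)
with open("genome.fa", "w") as fh:
    fh.write(f">{genome.name}\n{genome.seq}\n")
profile = MutationProfile(sub_rate=0.05, ins_rate=0.01, del_rate=0.01, rng_seed=2)
reads, truth = simulate_reads(genome, 2.0, 2000, 0.0, profile)
with open("reads.fq", "w") as fh:
    for r in reads:
        fh.write(f"@{r.name}\n{r.seq}\n+\n{r.qual}\n")
print(truth["read00000"])
# TruthInterval(seq_id='genome', start=40204, end=42204, strand='+')
```

```sh
$ fuzzyseed map genome.fa reads.fq --mode blend_i | head -3
read00000  2004  5   1997  +  genome  50000  40209  42197  2115  1992  40  cm:i:141  s1:i:2089
read00001  1991  11  1963  +  genome  50000  19874  21834  1950  1960  40  cm:i:130  s1:i:1916
read00002  2001  46  1997  -  genome  50000  16078  18029  1800  1951  40  cm:i:120  s1:i:1782
```

Each line is one chain in PAF: `read00000` (2004 bp after errors) maps on
the `+` strand to `genome[40209:42197]` — inside its true interval
`[40204, 42204)` — with 141 fuzzy seed matches (`cm`), 2115 matched seed
bases, chain score 2089 (`s1`), and mapping quality 40 (unique hit).
Despite ~7% error, the chain covers >99% of the read because similar seeds
still hash identically.

Other entry points: `fuzzyseed index` (persist an index), `fuzzyseed
overlap` (all-vs-all read overlapping, self-hits suppressed), `fuzzyseed
collide` (edit-distance histogram of non-identical same-hash seed pairs,
baseline vs fuzzy — the collision-skew diagnostic). Library use mirrors the
CLI: see `fuzzyseed.pipeline.map_queries` / `overlap_reads` and
`fuzzyseed.simeval` for the experiment drivers. Model details, parameter
meanings and defaults are in `docs/methods.md`.

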