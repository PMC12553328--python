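# Methods

## The scheduling model

Let the protein catalog be an ordered list of n unique identifiers.
`partition` assigns catalog positions to B contiguous blocks; with
r = n mod B, the first r blocks hold ⌈n/B⌉ proteins and the rest ⌊n/B⌋.
Contiguity is a deliberate choice (the assignment rule is otherwise
unconstrained): it makes each block load a single sequential scan of the
keyed store, and it means a canonically ordered pair (u, v) — lower
catalog position first — always lands in a normalized block pair
(block(u) ≤ block(v)) without extra bookkeeping.

`serpentine_schedule(B)` emits every block pair (i, j), i ≤ j, exactly
once: row i runs j = i..B when i is odd and j = B..i when i is even.
Consecutive steps therefore share a block except at the
diagonal-to-diagonal transition (i, i) → (i+1, i+1) at the end of an
even row, where the outgoing step holds only one block, so either way at
most one new block must be loaded per transition. With the eviction
policy below this caps residency at min(B, 3) blocks for any B.

**Eviction policy.** Before loading what step t needs, evict every
resident block required by neither step t−1 nor step t. Step t−1's
blocks are retained because its tasks may still be in flight while step
t's missing block is prefetched. Since |blocks(t−1) ∪ blocks(t)| ≤ 3
under the serpentine order, residency never exceeds three slots; total
loads are bounded by B(B+1)/2 + 1, so load volume in proteins is at most
(B(B+1)/2 + 1)·⌈n/B⌉ — linear in B for fixed n. The policy is
deterministic, which keeps schedules and their ledgers reproducible and
exportable (`schedule_table`).

`simulate_memory` replays a schedule's loads/evicts and certifies
integrity (a step whose blocks are not resident raises); it is how the
three-block and one-load bounds are tested rather than merely asserted.

Bipartite schedules tag blocks `("A", a)` / `("B", b)` so the two
catalogs' blocks never collide in the ledger, and traverse the p × q
grid with the same alternating column order; the first step loads two
blocks (one from each set), every later step at most one.

## Pair universes

Counting uses exact integer arithmetic: C(n, 2) all-pairs, m·n
bipartite, and cross-pair density 100·mn/C(m+n, 2) as an exact rational
before conversion to float. `sample_pair_fraction` draws
⌊fraction · C(n, 2)⌋ distinct unordered pairs; the floor is computed on
the exact rational value of the binary float `fraction`, so printed
sample sizes are reproduced even when the product exceeds float integer
precision. Pair indices are encoded colexicographically
(index(i, j) = C(j, 2) + i) and decoded with integer square roots, so
sampling never materializes the universe.

**Coverage guarantee.** Uniform sampling cannot guarantee that every
protein appears in a pair, so `ensure_coverage` applies a deterministic
repair after sampling: while some protein u is uncovered, find a sampled
pair with an endpoint of degree ≥ 2 and re-point that endpoint at u.
Such a pair always exists while k ≥ ⌈n/2⌉ (a sample where every
endpoint has degree 1 is a perfect matching, which would already cover
2k ≥ n proteins); smaller samples raise an infeasibility error. The
repair preserves the sample size and seed-determinism at the cost of a
slight departure from uniformity near the coverage boundary.

## The engine

The coordinator (the calling process) walks the schedule, performing the
annotated evicts/loads through a `MemoryAccountant` whose
`max_resident_blocks = min(B, 3)` bound is *enforcement*, not
bookkeeping: a load that would exceed it aborts the run with a
diagnostic. Pair tasks for each block pair are cut into chunks
(`chunk_size`, default 256 pairs) and placed on a queue bounded by
`buffer_capacity` (default 8 chunks), which is the backpressure contract
— the coordinator blocks rather than buffering unboundedly, and loading
of the next block overlaps scoring of the previous block pair. Workers
score pairs and push records to a second queue consumed by a single
writer process, which applies the threshold and writes
`<prefix>.tsv` (all pairs), `<prefix>.positive.tsv` (score ≥ threshold)
and, via the coordinator afterwards, a `<prefix>.log` summary. Both
below- and above-threshold predictions are persisted; the positives file
is the conventional thresholded output, the full file makes re-
thresholding free.

**By-value task transfer.** Each chunk carries copies of exactly the
embedding arrays its pairs reference, rather than references into a
shared-memory segment. This was chosen because Python's
`multiprocessing.shared_memory` attach-side resource tracking is fragile
across worker exits, and because it decouples eviction from worker
progress: once a chunk is enqueued, the coordinator may evict its blocks
without any completion barrier. The memory cost is bounded by
`buffer_capacity × chunk_size` pair payloads; the residency bound on
coordinator-held blocks is unaffected. A production scorer with large
embeddings would lower `chunk_size` or swap in shared memory behind the
same queue protocol.

**Failure semantics.** A worker that throws reports the offending pair,
then drains (and discards) remaining tasks so the coordinator never
deadlocks on a full queue; the run ends with a `WorkerError` rather than
a silently incomplete output — exactly-once delivery is a hard contract,
checked at the end of every run (`pairs_scored == pairs_requested`).
Missing embeddings are detected before any process starts.

**Determinism and ordering.** The mock scorer
`logistic(mean(E1) + mean(E2))` is a pure, symmetric function of the two
arrays (means accumulated in float64), so scores are bit-identical
across any (B, W); only row *order* is nondeterministic under W > 1
(completion order). Tests and the acceptance script therefore compare
record *sets* at the written 6-decimal precision; `--sorted` re-sorts
output canonically post-run.

**Sparse loading.** In sparse mode each executed block pair loads only
the proteins named by its candidate bucket, and those partial blocks are
evicted as soon as the step's chunks are enqueued; steps with empty
buckets never touch the store. Partial blocks are thus resident for
exactly one step (peak ≤ 2 partial blocks), trading repeated loads of
shared proteins for minimal residency — the right trade only for very
sparse candidate sets, which is why it is a flag and not the default.

**Modes and defaults.** `--blocks 1 --workers 1` reproduces the serial
behavior (and is the default); threshold defaults to 0.5 and values > 1
are allowed as a way to disable the positives file. All-pairs mode
excludes self-pairs (u, u) — this is what makes the pair universe
C(n, 2) — with an opt-in flag to include them. In bipartite mode pairs
are never canonicalized across sets (set-A id first), two stores or one
shared store are accepted, and ids shared between the catalogs resolve
to the set-A embedding with a warning.

## Synthetic data

`generate_synthetic_store` writes one (length, dim) float32
standard-normal dataset per id, lengths uniform on a configurable range,
all driven by one seeded generator (same seed ⇒ byte-identical store).
Defaults: dim 16–32 and lengths of tens of residues in fixtures — small
enough for exhaustive testing, structurally identical to real stores
(keyed container, variable lengths, float32). What the fixtures do *not*
emulate: realistic embedding geometry (language-model embeddings are
highly anisotropic), realistic length distributions, or any biological
signal in the scores. Green tests therefore establish that scheduling,
residency accounting, and exactly-once delivery are correct — not that
predictions are biologically meaningful, which is entirely the property
of the scorer plugged in.

## Numerical and interface choices

- Embeddings are stored and accounted as 4-byte floats; byte accounting
  is length × dim × 4 per protein, matching array `nbytes`.
- Scores are written with 6 decimal places; set comparisons use that
  precision.
- Block indices are 1-based in schedules, reports and errors; catalog
  positions are 0-based half-open internally.
- Duplicate rows in a pair file are de-duplicated silently with a logged
  count; self-pairs in a pair file are an error unless explicitly
  enabled.
- Catalog files are plain text (one id per line, `#` comments); FASTA is
  accepted with a maximum-length filter (default 1000 residues, the
  conventional cap for proteome-scale PPI inference).

## Known limitations

- No cost model for wall-clock time or hardware memory; the ledger
  counts blocks, proteins and bytes, not gigabytes on a given machine.
- No distributed (multi-node) scheduling; workers are processes on one
  host.
- The sparse mode re-loads proteins shared between adjacent block pairs
  rather than caching them across steps.
- Worker failure aborts the whole run; there is no per-pair retry.
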