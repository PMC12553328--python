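# ppiblocks

Memory-bounded, blocked, multi-worker pairwise inference for
protein–protein interaction (PPI) prediction.

## The problem

Proteome-scale PPI prediction scores every pair of proteins —
C(n, 2) = n(n−1)/2 pairs for n proteins — against per-protein embeddings
(one (length × dim) matrix per protein, produced upstream by a protein
language model). Preloading all embeddings is simple but needs memory
proportional to the whole proteome; loading each pair's embeddings
just-in-time thrashes the store. `ppiblocks` implements the middle
ground:

- the ordered protein catalog is split into **B contiguous, balanced
  blocks** (sizes differ by at most one);
- block pairs (i, j), i ≤ j, are visited in a **serpentine order**:
  odd rows ascend (j = i..B), even rows descend (j = B..i). Consecutive
  steps then always need at most **one block not already in memory**, so
  at most **three blocks are ever resident** — regardless of B;
- a **coordinator / worker-pool / single-writer** pipeline overlaps
  block loading with scoring: the coordinator loads blocks and enqueues
  chunks of pair tasks onto a bounded queue, W worker processes score
  pairs with a pluggable scorer, and one writer process thresholds and
  writes, so output files are never interleaved.

Peak embedding memory is ≈ 3·(n/B)·L̄·dim·4 bytes (L̄ the mean protein
length) instead of n·L̄·dim·4 — a B/3-fold reduction, at the cost of
re-loading blocks (total loads ≤ B(B+1)/2 + 1, i.e. load volume grows
linearly in B).

Four modes cover the common tasks: `all_pairs` (every unordered pair in
one catalog), `some_pairs` (an explicit candidate list), `sparse`
(candidate list, loading only the proteins each block pair actually
names), and `bipartite` (every cross pair between two catalogs, e.g. a
host and its symbiont, with separate embedding stores per set).

A **serial reference** implementation (preload everything, one process,
canonical order) defines correctness: for every (B, W) configuration the
engine's output record set is identical to it. The built-in scorer is a
deterministic mock — `logistic(mean(E1) + mean(E2))` — standing in for a
trained model; any object with a `score(array1, array2) -> float` method
can be plugged in.

## Worked example

```bash
# synthetic fixture: 12 proteins, 16-dim embeddings
ppiblocks make-fixtures --out-dir demo --n-proteins 12 --dim 16 --seed 1

# blocked all-pairs inference, 3 blocks, 2 workers
ppiblocks predict --proteins demo/proteins.txt \
    --embeddings demo/embeddings.h5 --blocks 3 --workers 2 -o demo/out
```

prints the run summary

```
mode	all_pairs
pairs_requested	66
pairs_scored	66
positives	15
peak_resident_blocks	3
total_block_loads	3
bytes_loaded	57280
output	demo/out.tsv
positive_output	demo/out.positive.tsv
```

All C(12, 2) = 66 pairs were scored exactly once; 15 scores cleared the
0.5 threshold into `demo/out.positive.tsv`; and although there are 3
blocks and 6 block pairs, only 3 block loads happened and never more
than 3 blocks sat in memory. The score file starts

```
id1	id2	score
P08EC18	P8306B8	0.493378
P08EC18	PDE786F	0.493647
P08EC18	PD2AC6B	0.479946
```

Planning is independent of any embeddings. For a 6282-protein catalog
split into 64 blocks:

```bash
ppiblocks plan --count 6282 --blocks 64
```

```
steps	2080
peak_resident_blocks	3
total_block_loads	2017
load_volume_proteins	197717
```

2080 block-pair steps (C(64,2)+64), yet the serpentine order keeps peak
residency at 3 blocks (~300 of 6282 proteins in memory at once).

Other subcommands: `predict_serial` (the preload-everything reference),
`predict_bipartite --proteins1 a.txt --proteins2 b.txt [--embeddings2 b.h5]`
for cross-proteome prediction, and `predict --pairs pairs.tsv
[--sparse_loading]` for candidate lists.

## Acceptance script

`scripts/acceptance.py` re-runs the package end to end from scratch: it
generates a synthetic catalog and store, certifies the serpentine
schedule's residency and load bounds by ledger simulation, executes all
four engine modes, and verifies each output set against the serial
reference, writing its JSON result to `--out`:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
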