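"""Blocked, multi-worker pairwise inference engine.

Architecture (one run):

* the coordinator (the calling process) walks the serpentine block-pair
  schedule, loading at most one new block per step through a
  :class:`~ppiblocks.embedding_store.MemoryAccountant` that enforces the
  min(B, 3) resident-block bound, and enqueues chunks of pair tasks onto
  a bounded queue while workers are still scoring the previous block
  pair;
* ``n_workers`` worker processes pull chunks, score each pair with a
  pluggable scorer, and push prediction records to a second queue;
* a single writer process thresholds and writes records, so output files
  have exactly one writer and progress is monotone.

Task chunks carry their own copies of the embedding arrays they need, so
workers never touch the store and eviction in the coordinator can never
invalidate an in-flight task. The serial reference implementation
(preload everything, iterate pairs in canonical order, one process) is
the correctness oracle: for any (B, W) the engine's output record set is
identical to it, because the scorer is deterministic.
"""

from __future__ import annotations

import logging
import math
import multiprocessing as mp
import os
import traceback
from dataclasses import dataclass, field
from typing import Iterable, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from . import block_plan, embedding_store, pair_modes
from .block_plan import BlockPairSchedule, BlockPartition, ProteinCatalog
from .embedding_store import (
    EmbeddingRecord,
    EmbeddingStore,
    MemoryAccountant,
    evict_block,
    load_block,
)
from .pair_modes import MODES, CandidatePairSet, PairBuckets

logger = logging.getLogger("ppiblocks")

__all__ = [
    "EngineConfig",
    "PredictionRecord",
    "RunSummary",
    "MockScorer",
    "ScorerError",
    "WorkerError",
    "score_pair",
    "serial_reference",
    "run",
    "write_predictions",
    "read_predictions",
]

DEFAULT_THRESHOLD = 0.5
SCORE_DECIMALS = 6
HEADER = ("id1", "id2", "score")


class ScorerError(ValueError):
    """Embedding shape incompatible with the scorer's declared dimension."""


class WorkerError(RuntimeError):
    """A scoring worker failed; the run is aborted rather than incomplete."""


class PredictionRecord(NamedTuple):
    id1: str
    id2: str
    score: float


@dataclass
class EngineConfig:
    """Run configuration for the blocked engine.

    ``buffer_capacity`` bounds the number of task chunks the coordinator
    may have enqueued-but-unconsumed at any time (backpressure);
    ``chunk_size`` is the number of pair tasks shipped per chunk.
    """

    mode: str = "all_pairs"
    n_blocks: int = 1
    n_workers: int = 1
    threshold: float = DEFAULT_THRESHOLD
    buffer_capacity: int = 8
    chunk_size: int = 256
    output_prefix: str = "predictions"
    seed: int = 0
    n_blocks_b: Optional[int] = None  # column-set blocks (bipartite only)
    include_self: bool = False
    sorted_output: bool = False

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.n_blocks < 1:
            raise ValueError(f"n_blocks must be >= 1, got {self.n_blocks}")
        if self.n_workers < 1:
            raise ValueError(f"n_workers must be >= 1, got {self.n_workers}")
        if self.threshold < 0.0:
            # > 1 is permitted: it cleanly disables the positives file
            raise ValueError(f"threshold must be >= 0, got {self.threshold}")
        if self.buffer_capacity < 1:
            raise ValueError("buffer capacity must be >= 1")
        if self.chunk_size < 1:
            raise ValueError("chunk size must be >= 1")


@dataclass(frozen=True)
class RunSummary:
    """What a run did: counts, residency peak, and load totals."""

    mode: str
    pairs_requested: int
    pairs_scored: int
    positives: int
    peak_resident_blocks: int
    total_loads: int
    bytes_loaded: int
    output_path: str
    positive_path: str

    def as_text(self) -> str:
        lines = [
            f"mode\t{self.mode}",
            f"pairs_requested\t{self.pairs_requested}",
            f"pairs_scored\t{self.pairs_scored}",
            f"positives\t{self.positives}",
            f"peak_resident_blocks\t{self.peak_resident_blocks}",
            f"total_block_loads\t{self.total_loads}",
            f"bytes_loaded\t{self.bytes_loaded}",
            f"output\t{self.output_path}",
            f"positive_output\t{self.positive_path}",
        ]
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MockScorer:
    """Deterministic stand-in for a trained pairwise interaction model.

    score(E1, E2) = logistic(mean(E1) + mean(E2)): symmetric under
    argument swap, spans (0, 1), cheap, and a pure function of the two
    arrays — exactly what the scheduling layer needs from a model and
    nothing more. ``dim`` (when set) is the embedding dimensionality the
    scorer insists on.
    """

    dim: Optional[int] = None

    def score(self, array1: np.ndarray, array2: np.ndarray) -> float:
        for a in (array1, array2):
            if a.ndim != 2 or a.size == 0:
                raise ScorerError(f"expected non-empty (length, dim) array, got shape {a.shape}")
            if self.dim is not None and a.shape[1] != self.dim:
                raise ScorerError(
                    f"embedding dim {a.shape[1]} does not match scorer dim {self.dim}"
                )
        if array1.shape[1] != array2.shape[1]:
            raise ScorerError(
                f"embedding dims differ: {array1.shape[1]} vs {array2.shape[1]}"
            )
        z = float(np.mean(array1, dtype=np.float64) + np.mean(array2, dtype=np.float64))
        return 1.0 / (1.0 + math.exp(-z))


def score_pair(scorer, record1: EmbeddingRecord, record2: EmbeddingRecord) -> float:
    """Score one pair of resident embedding records."""
    return scorer.score(record1.array, record2.array)


# ---------------------------------------------------------------------------
# Output writing
# ---------------------------------------------------------------------------


def _paths(prefix: str) -> Tuple[str, str]:
    return f"{prefix}.tsv", f"{prefix}.positive.tsv"


def write_predictions(
    records: Iterable[PredictionRecord], threshold: float, output_prefix: str
) -> Tuple[int, int]:
    """Write the full score TSV and the above-threshold positives TSV.

    Returns (records written, positives). Both files exist even for an
    empty stream; a positive is a record with score >= threshold.
    """
    full_path, pos_path = _paths(output_prefix)
    n = n_pos = 0
    with open(full_path, "w") as full, open(pos_path, "w") as pos:
        header = "\t".join(HEADER) + "\n"
        full.write(header)
        pos.write(header)
        for rec in records:
            line = f"{rec.id1}\t{rec.id2}\t{rec.score:.{SCORE_DECIMALS}f}\n"
            full.write(line)
            n += 1
            if rec.score >= threshold:
                pos.write(line)
                n_pos += 1
    return n, n_pos


def read_predictions(path) -> List[PredictionRecord]:
    """Read a predictions TSV back into records (scores as written)."""
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            id1, id2, score = line.rstrip("\n").split("\t")
            out.append(PredictionRecord(id1, id2, float(score)))
    return out


def _sort_outputs(prefix: str, pos_key) -> None:
    for path in _paths(prefix):
        recs = read_predictions(path)
        recs.sort(key=pos_key)
        with open(path, "w") as fh:
            fh.write("\t".join(HEADER) + "\n")
            for r in recs:
                fh.write(f"{r.id1}\t{r.id2}\t{r.score:.{SCORE_DECIMALS}f}\n")


# ---------------------------------------------------------------------------
# Serial reference (the oracle)
# ---------------------------------------------------------------------------


def serial_reference(
    catalog: ProteinCatalog,
    store: EmbeddingStore,
    scorer,
    pairs: Optional[CandidatePairSet] = None,
    catalog_b: Optional[ProteinCatalog] = None,
    store_b: Optional[EmbeddingStore] = None,
    include_self: bool = False,
) -> List[PredictionRecord]:
    """Single-process reference: preload everything, score pairs in order.

    Enumerates the requested pair universe in canonical catalog order —
    all unordered distinct pairs by default, an explicit candidate set
    when ``pairs`` is given, or the full cross product when a second
    catalog is supplied. This is the correctness oracle for every
    blocked/parallel configuration.
    """
    emb = {pid: EmbeddingRecord(pid, store.get(pid)) for pid in catalog.ids}
    if catalog_b is not None:
        sb = store_b if store_b is not None else store
        emb_b = {pid: EmbeddingRecord(pid, sb.get(pid)) for pid in catalog_b.ids}
        task_iter = [
            (u, v) for u in catalog.ids for v in catalog_b.ids
        ]
        lookup = lambda u, v: (emb[u], emb_b[v])
    elif pairs is not None:
        task_iter = pairs.sorted()
        lookup = lambda u, v: (emb[u], emb[v])
    else:
        ids = catalog.ids
        task_iter = [
            (ids[a], ids[b]) for a in range(len(ids)) for b in range(a + 1, len(ids))
        ]
        if include_self:
            task_iter = sorted(
                task_iter + [(u, u) for u in ids],
                key=lambda p: (catalog.position(p[0]), catalog.position(p[1])),
            )
        lookup = lambda u, v: (emb[u], emb[v])
    return [
        PredictionRecord(u, v, score_pair(scorer, *lookup(u, v))) for u, v in task_iter
    ]


# ---------------------------------------------------------------------------
# Worker-pool engine
# ---------------------------------------------------------------------------

_SENTINEL = None


def _worker_loop(task_queue, result_queue, scorer):
    """Score chunks of pair tasks until the coordinator sends the sentinel.

    On failure the worker reports the offending pair and keeps draining
    the queue (discarding tasks) so the coordinator never deadlocks; the
    run is aborted by the caller once the failure is seen.
    """
    failed = False
    while True:
        task = task_queue.get()
        if task is _SENTINEL:
            result_queue.put(("worker_done", os.getpid()))
            return
        if failed:
            continue
        pair_list, arrays = task
        records = []
        try:
            for u, v in pair_list:
                records.append((u, v, scorer.score(arrays[u], arrays[v])))
        except Exception as exc:  # fail-fast: report, then drain
            result_queue.put(
                ("error", f"scoring pair ({u!r}, {v!r}): {exc}\n{traceback.format_exc()}")
            )
            failed = True
            continue
        result_queue.put(("records", records))


def _writer_loop(result_queue, summary_queue, n_workers, threshold, output_prefix):
    """Single writer: threshold, write, count — then report a summary."""
    full_path, pos_path = _paths(output_prefix)
    n = n_pos = 0
    errors = []
    done = 0
    with open(full_path, "w") as full, open(pos_path, "w") as pos:
        header = "\t".join(HEADER) + "\n"
        full.write(header)
        pos.write(header)
        while done < n_workers:
            kind, payload = result_queue.get()
            if kind == "worker_done":
                done += 1
            elif kind == "error":
                errors.append(payload)
            else:
                for u, v, score in payload:
                    line = f"{u}\t{v}\t{score:.{SCORE_DECIMALS}f}\n"
                    full.write(line)
                    n += 1
                    if score >= threshold:
                        pos.write(line)
                        n_pos += 1
    summary_queue.put({"pairs_scored": n, "positives": n_pos, "errors": errors})


def _chunked(seq: Sequence, size: int):
    for start in range(0, len(seq), size):
        yield seq[start : start + size]


def _requested_count(mode, catalog, pairs, catalog_b, include_self) -> int:
    if mode == "all_pairs":
        n = block_plan.count_all_pairs(len(catalog))
        return n + (len(catalog) if include_self else 0)
    if mode == "bipartite":
        return block_plan.count_bipartite_pairs(len(catalog), len(catalog_b))
    return len(pairs)


def run(
    config: EngineConfig,
    catalog: ProteinCatalog,
    store_path,
    scorer,
    pairs: Optional[CandidatePairSet] = None,
    catalog_b: Optional[ProteinCatalog] = None,
    store_path_b=None,
) -> RunSummary:
    """Execute one blocked, multi-worker inference run.

    Scores every requested pair exactly once and writes
    ``<prefix>.tsv`` / ``<prefix>.positive.tsv`` / ``<prefix>.log``;
    output row order is completion order unless ``sorted_output`` is set.
    Raises on missing embeddings before any scoring starts, and raises
    :class:`WorkerError` (aborting the run) if any worker fails.
    """
    mode = config.mode
    if mode in ("some_pairs", "sparse") and pairs is None:
        raise ValueError(f"mode {mode!r} requires a candidate pair set")
    if mode == "bipartite" and catalog_b is None:
        raise ValueError("bipartite mode requires a second catalog")

    store = embedding_store.open_store(store_path)
    store_b = (
        embedding_store.open_store(store_path_b)
        if store_path_b is not None
        else store
    )

    # --- plan -------------------------------------------------------------
    part = block_plan.partition(catalog, config.n_blocks)
    part_b = None
    buckets: Optional[PairBuckets] = None
    if mode == "bipartite":
        q = config.n_blocks_b if config.n_blocks_b is not None else config.n_blocks
        part_b = block_plan.partition(catalog_b, min(q, len(catalog_b)))
        schedule = block_plan.bipartite_schedule(part.n_blocks, part_b.n_blocks)
        residency_bound = min(part.n_blocks + part_b.n_blocks, 3)
    else:
        schedule = block_plan.serpentine_schedule(part.n_blocks)
        residency_bound = min(part.n_blocks, 3)
        if mode in ("some_pairs", "sparse"):
            buckets = pair_modes.bucket_pairs(pairs, part)

    # --- pre-run validation ----------------------------------------------
    if mode == "sparse":
        required = sorted({p for pair in pairs for p in pair})
    else:
        required = list(catalog.ids)
    absent = store.missing(required)
    if absent:
        raise embedding_store.MissingProteinError(
            f"proteins absent from store: {absent[:10]}"
            + (f" (+{len(absent) - 10} more)" if len(absent) > 10 else "")
        )
    if mode == "bipartite":
        absent_b = store_b.missing(catalog_b.ids)
        if absent_b:
            raise embedding_store.MissingProteinError(
                f"proteins absent from second store: {absent_b[:10]}"
            )

    requested = _requested_count(mode, catalog, pairs, catalog_b, config.include_self)
    accountant = MemoryAccountant(max_resident_blocks=residency_bound)

    # --- processes --------------------------------------------------------
    ctx = mp.get_context("fork") if "fork" in mp.get_all_start_methods() else mp.get_context()
    task_queue = ctx.Queue(maxsize=config.buffer_capacity)
    result_queue = ctx.Queue()
    summary_queue = ctx.Queue()
    writer = ctx.Process(
        target=_writer_loop,
        args=(result_queue, summary_queue, config.n_workers, config.threshold,
              config.output_prefix),
    )
    workers = [
        ctx.Process(target=_worker_loop, args=(task_queue, result_queue, scorer))
        for _ in range(config.n_workers)
    ]
    writer.start()
    for w in workers:
        w.start()

    def enqueue_step(step, tasks, resident_lookup):
        for chunk in _chunked(tasks, config.chunk_size):
            needed = {p for pair in chunk for p in pair}
            arrays = {pid: resident_lookup(pid).array for pid in needed}
            task_queue.put((chunk, arrays))  # blocks on backpressure

    try:
        if mode == "sparse":
            _drive_sparse(config, catalog, part, buckets, schedule, store,
                          accountant, enqueue_step)
        elif mode == "bipartite":
            _drive_bipartite(config, catalog, part, catalog_b, part_b, schedule,
                             store, store_b, accountant, enqueue_step)
        else:
            _drive_full(config, catalog, part, buckets, schedule, store,
                        accountant, mode, enqueue_step)
    finally:
        for _ in workers:
            task_queue.put(_SENTINEL)
        for w in workers:
            w.join()
        summary = summary_queue.get()
        writer.join()
        store.close()
        if store_b is not store:
            store_b.close()

    if summary["errors"]:
        raise WorkerError(
            f"{len(summary['errors'])} worker failure(s); run aborted. First:\n"
            + summary["errors"][0]
        )

    full_path, pos_path = _paths(config.output_prefix)
    if config.sorted_output:
        if mode == "bipartite":
            key = lambda r: (catalog.position(r.id1), catalog_b.position(r.id2))
        else:
            key = lambda r: (catalog.position(r.id1), catalog.position(r.id2))
        _sort_outputs(config.output_prefix, key)

    result = RunSummary(
        mode=mode,
        pairs_requested=requested,
        pairs_scored=summary["pairs_scored"],
        positives=summary["positives"],
        peak_resident_blocks=accountant.peak_resident_blocks,
        total_loads=accountant.total_loads,
        bytes_loaded=accountant.total_bytes_loaded,
        output_path=full_path,
        positive_path=pos_path,
    )
    with open(f"{config.output_prefix}.log", "w") as fh:
        fh.write(result.as_text())
    if result.pairs_scored != result.pairs_requested:
        raise WorkerError(
            f"scored {result.pairs_scored} of {result.pairs_requested} requested pairs"
        )
    return result


def _drive_full(config, catalog, part, buckets, schedule, store, accountant,
                mode, enqueue_step):
    """All-pairs / some-pairs driver: whole blocks, schedule-driven eviction."""
    for t, step in enumerate(schedule):
        for b in step.evicts:
            evict_block(accountant, b)
        for b in step.loads:
            load_block(store, part, catalog, b, accountant=accountant)
        tasks = pair_modes.enumerate_step_pairs(
            mode, step, catalog, part, buckets=buckets,
            include_self=config.include_self,
        )
        if tasks:
            resident = {}
            for b in step.blocks:
                resident.update(accountant.get(b).records)
            enqueue_step(step, tasks, resident.__getitem__)
        logger.info("block pair (%d, %d): %d pair task(s) enqueued", step.i, step.j,
                    len(tasks))
    for b in list(accountant.resident_blocks):
        evict_block(accountant, b)


def _drive_sparse(config, catalog, part, buckets, schedule, store, accountant,
                  enqueue_step):
    """Sparse driver: load only each step's named proteins, evict after enqueue.

    Steps with empty buckets are skipped without touching the store, so
    residency never exceeds the two partial blocks of the current step.
    """
    for step in schedule:
        sel_i, sel_j = pair_modes.sparse_selection(buckets, (step.i, step.j))
        tasks = pair_modes.enumerate_step_pairs(
            "sparse", step, catalog, part, buckets=buckets
        )
        if not tasks:
            continue
        loaded = []
        load_block(store, part, catalog, step.i,
                   selection=sorted(sel_i, key=catalog.position),
                   accountant=accountant)
        loaded.append(step.i)
        if step.j != step.i:
            load_block(store, part, catalog, step.j,
                       selection=sorted(sel_j, key=catalog.position),
                       accountant=accountant)
            loaded.append(step.j)
        resident = {}
        for b in loaded:
            resident.update(accountant.get(b).records)
        enqueue_step(step, tasks, resident.__getitem__)
        for b in loaded:
            evict_block(accountant, b)
        logger.info("block pair (%d, %d): %d sparse pair task(s) enqueued",
                    step.i, step.j, len(tasks))


def _drive_bipartite(config, catalog, part, catalog_b, part_b, schedule,
                     store, store_b, accountant, enqueue_step):
    """Bipartite driver: row-set blocks from one store, column-set from the other."""
    for step in schedule:
        for b in step.evicts:
            evict_block(accountant, b)
        for b in step.loads:
            tag, idx = b
            if tag == "A":
                load_block(store, part, catalog, idx, accountant=accountant,
                           block_id=b)
            else:
                load_block(store_b, part_b, catalog_b, idx, accountant=accountant,
                           block_id=b)
        tasks = pair_modes.enumerate_step_pairs(
            "bipartite", step, catalog, part,
            catalog_b=catalog_b, partition_b=part_b,
        )
        if tasks:
            resident = {}
            # B first so that, for ids shared across catalogs, the set-A
            # embedding takes precedence (documented first-set precedence)
            for b in sorted(step.blocks, reverse=True):
                resident.update(accountant.get(b).records)
            enqueue_step(step, tasks, resident.__getitem__)
        logger.info("block pair (A%d, B%d): %d pair task(s) enqueued", step.i,
                    step.j, len(tasks))
    for b in list(accountant.resident_blocks):
        evict_block(accountant, b)
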