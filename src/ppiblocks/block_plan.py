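"""Blocked pair-universe combinatorics and serpentine block-pair scheduling.

This module is the pure planning core of the package: it knows how to
count and sample protein-pair universes, how to split an ordered protein
catalog into contiguous balanced blocks, how to order block pairs so that
consecutive steps never need more than one block that is not already in
memory, and how to replay a schedule against a memory ledger to certify
the residency and load bounds.

Everything here is deterministic, exact-integer arithmetic (no floats in
the counting paths) and independent of any on-disk store: block identities
are 1-based integers for single-catalog schedules and ``("A", a)`` /
``("B", b)`` tags for bipartite schedules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "ProteinCatalog",
    "BlockPartition",
    "BlockPairStep",
    "BlockPairSchedule",
    "MemoryLedger",
    "InfeasibleCoverageError",
    "ScheduleIntegrityError",
    "count_all_pairs",
    "count_bipartite_pairs",
    "pair_density_percent",
    "sample_size",
    "sample_pair_fraction",
    "partition",
    "serpentine_schedule",
    "bipartite_schedule",
    "simulate_memory",
    "schedule_table",
]

BlockId = Union[int, tuple]


class InfeasibleCoverageError(ValueError):
    """Requested sample is too small for every protein to appear in a pair."""


class ScheduleIntegrityError(RuntimeError):
    """A schedule step would execute without its blocks resident."""


# ---------------------------------------------------------------------------
# Catalogs and partitions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinCatalog:
    """Ordered list of unique protein identifiers with residue lengths.

    The catalog order is the canonical order for everything downstream:
    it defines block assignment, the canonical orientation of a pair
    (lower catalog position first), and the serial iteration order.
    """

    ids: tuple
    lengths: tuple

    def __post_init__(self):
        ids = tuple(self.ids)
        lengths = tuple(int(x) for x in self.lengths)
        if len(ids) != len(lengths):
            raise ValueError(
                f"ids ({len(ids)}) and lengths ({len(lengths)}) differ in length"
            )
        if len(set(ids)) != len(ids):
            seen: set = set()
            dups = [i for i in ids if i in seen or seen.add(i)]
            raise ValueError(f"duplicate protein ids: {sorted(set(dups))[:5]}")
        if any(l <= 0 for l in lengths):
            raise ValueError("all protein lengths must be strictly positive")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "lengths", lengths)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def index(self) -> Mapping[str, int]:
        """Mapping from protein id to 0-based catalog position (cached)."""
        cached = self.__dict__.get("_index")
        if cached is None:
            cached = {pid: i for i, pid in enumerate(self.ids)}
            self.__dict__["_index"] = cached
        return cached

    def position(self, protein_id: str) -> int:
        try:
            return self.index[protein_id]
        except KeyError:
            raise KeyError(f"protein id not in catalog: {protein_id!r}") from None


@dataclass(frozen=True)
class BlockPartition:
    """Contiguous balanced assignment of catalog positions to blocks.

    ``boundaries`` holds B+1 monotone positions; block ``i`` (1-based)
    covers the half-open slice ``[boundaries[i-1], boundaries[i])``.
    The first ``size mod B`` blocks are one protein larger than the rest.
    """

    n_blocks: int
    boundaries: tuple

    def __post_init__(self):
        b = tuple(int(x) for x in self.boundaries)
        if len(b) != self.n_blocks + 1:
            raise ValueError("boundaries must have n_blocks + 1 entries")
        if any(b[i] > b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("boundaries must be monotone non-decreasing")
        object.__setattr__(self, "boundaries", b)

    @property
    def size(self) -> int:
        """Number of catalog positions covered."""
        return self.boundaries[-1] - self.boundaries[0]

    def block_range(self, block_index: int) -> tuple:
        """Half-open (start, stop) catalog positions of a 1-based block."""
        if not 1 <= block_index <= self.n_blocks:
            raise ValueError(
                f"block index {block_index} out of range 1..{self.n_blocks}"
            )
        return self.boundaries[block_index - 1], self.boundaries[block_index]

    def block_size(self, block_index: int) -> int:
        start, stop = self.block_range(block_index)
        return stop - start

    @property
    def sizes(self) -> tuple:
        return tuple(self.block_size(i) for i in range(1, self.n_blocks + 1))

    def block_of(self, position: int) -> int:
        """1-based block index containing a 0-based catalog position."""
        if not self.boundaries[0] <= position < self.boundaries[-1]:
            raise ValueError(f"catalog position {position} outside partition")
        # bisect_right on boundaries; B is small so np.searchsorted is fine
        return int(np.searchsorted(self.boundaries, position, side="right"))

    def members(self, block_index: int, catalog: ProteinCatalog) -> tuple:
        start, stop = self.block_range(block_index)
        return catalog.ids[start:stop]


def partition(catalog, n_blocks: int) -> BlockPartition:
    """Split a catalog (or a bare size) into contiguous balanced blocks.

    The first ``size mod B`` blocks get ``ceil(size/B)`` proteins, the rest
    ``floor(size/B)``; sizes therefore differ by at most one and the slices
    cover the catalog in order.
    """
    size = catalog if isinstance(catalog, int) else len(catalog)
    if n_blocks < 1:
        raise ValueError(f"n_blocks must be >= 1, got {n_blocks}")
    if n_blocks > size:
        raise ValueError(
            f"n_blocks ({n_blocks}) exceeds catalog size ({size})"
        )
    base, extra = divmod(size, n_blocks)
    boundaries = [0]
    for i in range(n_blocks):
        boundaries.append(boundaries[-1] + base + (1 if i < extra else 0))
    return BlockPartition(n_blocks=n_blocks, boundaries=tuple(boundaries))


# ---------------------------------------------------------------------------
# Pair-universe counting and sampling
# ---------------------------------------------------------------------------


def _check_count(n, name: str) -> int:
    if n != int(n):
        raise ValueError(f"{name} must be an integer, got {n!r}")
    n = int(n)
    if n < 0:
        raise ValueError(f"{name} must be non-negative, got {n}")
    return n


def count_all_pairs(n) -> int:
    """Number of unordered pairs of distinct proteins among ``n``: n(n-1)/2."""
    n = _check_count(n, "protein count")
    return n * (n - 1) // 2


def count_bipartite_pairs(m, n) -> int:
    """Number of cross pairs between disjoint sets of sizes ``m`` and ``n``."""
    m = _check_count(m, "set-A count")
    n = _check_count(n, "set-B count")
    return m * n


def pair_density_percent(m, n) -> float:
    """Cross-pair count as a percentage of the full unordered pair universe.

    The universe is all C(m+n, 2) unordered pairs of the pooled m+n
    proteins; the numerator is the m*n cross pairs. Callers typically
    round to an integer percent.
    """
    m = _check_count(m, "set-A count")
    n = _check_count(n, "set-B count")
    universe = count_all_pairs(m + n)
    if universe == 0:
        raise ValueError("pair universe is empty (m + n < 2)")
    return float(100 * Fraction(m * n, universe))


def sample_size(n: int, fraction: float) -> int:
    """Exact ``floor(fraction * C(n, 2))`` for a given sampling fraction.

    Uses the exact rational value of the binary float ``fraction`` so the
    result is correct even when the product exceeds float integer
    precision.
    """
    n = _check_count(n, "protein count")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    return int(Fraction(fraction) * count_all_pairs(n))


def _decode_pair_index(e: int) -> tuple:
    # colexicographic: pair (i, j), i < j, has index C(j,2) + i
    j = (1 + math.isqrt(1 + 8 * e)) // 2
    if j * (j - 1) // 2 > e:  # guard isqrt boundary
        j -= 1
    i = e - j * (j - 1) // 2
    return i, j


def sample_pair_fraction(
    n: int,
    fraction: float,
    seed: int = 0,
    ensure_coverage: bool = False,
):
    """Uniformly sample ``floor(fraction * C(n,2))`` distinct unordered pairs.

    Pairs are returned as a sorted list of 0-based position tuples
    ``(i, j)`` with ``i < j``; the same seed always yields the same list.

    With ``ensure_coverage`` every protein is guaranteed to appear in at
    least one sampled pair: after uniform sampling, pairs with an endpoint
    of degree >= 2 are deterministically re-pointed at uncovered proteins.
    This keeps the sample size and determinism exact at the cost of a
    slight departure from uniformity. If the sample is smaller than
    ``ceil(n/2)`` coverage is impossible and an error is raised.
    """
    n = _check_count(n, "protein count")
    if n < 2:
        raise ValueError(f"need at least 2 proteins to sample pairs, got {n}")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    universe = count_all_pairs(n)
    k = sample_size(n, fraction)
    if ensure_coverage and k < math.ceil(n / 2):
        raise InfeasibleCoverageError(
            f"sample of {k} pairs cannot cover all {n} proteins "
            f"(need at least {math.ceil(n / 2)})"
        )

    rng = np.random.default_rng(seed)
    if universe <= 2_000_000:
        idx = rng.choice(universe, size=k, replace=False)
    else:
        # rejection-sample distinct indices; switch to complement when dense
        want_complement = k > universe // 2
        target = universe - k if want_complement else k
        chosen = set()
        while len(chosen) < target:
            batch = rng.integers(0, universe, size=max(target - len(chosen), 1024))
            for e in batch:
                chosen.add(int(e))
                if len(chosen) == target:
                    break
        if want_complement:
            idx = np.array([e for e in range(universe) if e not in chosen])
        else:
            idx = np.fromiter(chosen, dtype=np.int64)
    pairs = sorted(_decode_pair_index(int(e)) for e in idx)

    if ensure_coverage:
        pairs = _repair_coverage(pairs, n)
    return pairs


def _repair_coverage(pairs, n: int):
    """Re-point pairs so every protein 0..n-1 has degree >= 1."""
    degree = np.zeros(n, dtype=np.int64)
    for i, j in pairs:
        degree[i] += 1
        degree[j] += 1
    uncovered = [p for p in range(n) if degree[p] == 0]
    if not uncovered:
        return pairs
    pair_set = set(pairs)
    for u in uncovered:
        # find a pair with an endpoint of degree >= 2 to donate a slot;
        # guaranteed to exist while len(pairs) >= ceil(n/2)
        donor = None
        for p in pairs:
            a, b = p
            if degree[a] >= 2 or degree[b] >= 2:
                donor = p
                break
        if donor is None:  # pragma: no cover - unreachable when k >= ceil(n/2)
            raise InfeasibleCoverageError(
                f"cannot repair coverage for protein {u} with {len(pairs)} pairs"
            )
        a, b = donor
        keep, drop = (b, a) if degree[a] >= 2 else (a, b)
        replacement = (min(keep, u), max(keep, u))
        pair_set.discard(donor)
        pair_set.add(replacement)
        degree[drop] -= 1
        degree[u] += 1
        pairs = sorted(pair_set)
    return sorted(pair_set)


# ---------------------------------------------------------------------------
# Serpentine schedules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlockPairStep:
    """One scheduled block pair with the loads/evicts performed before it.

    ``i``/``j`` are 1-based block indices (``i <= j`` in single-catalog
    schedules; row-set and column-set indices in bipartite schedules).
    ``blocks`` names the block identities this step needs resident.
    """

    i: int
    j: int
    blocks: frozenset
    loads: frozenset
    evicts: frozenset


@dataclass(frozen=True)
class BlockPairSchedule:
    """Ordered block-pair steps; every admissible pair appears exactly once."""

    steps: tuple
    kind: str  # "all_pairs" or "bipartite"

    def __len__(self) -> int:
        return len(self.steps)

    def __iter__(self):
        return iter(self.steps)


def _annotate(pair_list, needs, kind: str) -> BlockPairSchedule:
    """Attach loads/evicts to an ordered block-pair traversal.

    Eviction policy: before loading what step t needs, evict every
    resident block required by neither step t-1 (possibly still in
    flight) nor step t. With a serpentine traversal this keeps residency
    within 3 block slots and at most one load per step after the first.
    """
    resident: set = set()
    steps = []
    for t, ((i, j), need) in enumerate(zip(pair_list, needs)):
        if t == 0:
            evicts: frozenset = frozenset()
        else:
            keep = needs[t - 1] | need
            evicts = frozenset(resident - keep)
        resident -= evicts
        loads = frozenset(need - resident)
        resident |= loads
        steps.append(
            BlockPairStep(i=i, j=j, blocks=frozenset(need), loads=loads, evicts=evicts)
        )
    return BlockPairSchedule(steps=tuple(steps), kind=kind)


def serpentine_schedule(n_blocks: int) -> BlockPairSchedule:
    """All-pairs block schedule: odd rows ascend, even rows descend.

    Emits every (i, j) with 1 <= i <= j <= B exactly once. Row i is
    traversed with j running i..B when i is odd and B..i when i is even,
    so consecutive steps share at least one block and at most one new
    block is loaded per transition — the property that caps residency at
    three blocks.
    """
    if n_blocks < 1:
        raise ValueError(f"n_blocks must be >= 1, got {n_blocks}")
    order = []
    for i in range(1, n_blocks + 1):
        cols = range(i, n_blocks + 1) if i % 2 == 1 else range(n_blocks, i - 1, -1)
        order.extend((i, j) for j in cols)
    needs = [frozenset((i, j)) for i, j in order]
    return _annotate(order, needs, kind="all_pairs")


def bipartite_schedule(p: int, q: int) -> BlockPairSchedule:
    """Cross-catalog block schedule over p row-set and q column-set blocks.

    Block identities are tagged ``("A", a)`` and ``("B", b)`` so the two
    catalogs' blocks never collide in the residency ledger.
    """
    if p < 1 or q < 1:
        raise ValueError(f"block counts must be >= 1, got ({p}, {q})")
    order = []
    for a in range(1, p + 1):
        cols = range(1, q + 1) if a % 2 == 1 else range(q, 0, -1)
        order.extend((a, b) for b in cols)
    needs = [frozenset({("A", a), ("B", b)}) for a, b in order]
    return _annotate(order, needs, kind="bipartite")


# ---------------------------------------------------------------------------
# Memory-ledger simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MemoryLedger:
    """Replay record of a schedule's loads and evictions.

    ``load_volume_proteins``/``load_volume_bytes`` are only populated when
    block sizes (and per-protein byte sizes) are supplied to
    :func:`simulate_memory`.
    """

    resident_trace: tuple
    peak_resident_blocks: int
    total_loads: int
    load_volume_proteins: Optional[int] = None
    load_volume_bytes: Optional[int] = None


def simulate_memory(
    schedule: BlockPairSchedule,
    block_sizes: Optional[Mapping[BlockId, int]] = None,
    block_bytes: Optional[Mapping[BlockId, int]] = None,
) -> MemoryLedger:
    """Replay a schedule's loads/evicts and certify its integrity.

    Raises :class:`ScheduleIntegrityError` if a step would evict a
    non-resident block, re-load a resident one, or execute while one of
    its own blocks is absent. For all-pairs serpentine schedules the
    resulting peak residency is <= min(B, 3) and total loads <=
    B(B+1)/2 + 1.
    """
    resident: set = set()
    trace = []
    total_loads = 0
    volume_p = 0 if block_sizes is not None else None
    volume_b = 0 if block_bytes is not None else None
    for t, step in enumerate(schedule):
        if not step.evicts <= resident:
            raise ScheduleIntegrityError(
                f"step {t}: evicting non-resident block(s) {set(step.evicts) - resident}"
            )
        resident -= step.evicts
        if step.loads & resident:
            raise ScheduleIntegrityError(
                f"step {t}: re-loading resident block(s) {set(step.loads) & resident}"
            )
        resident |= step.loads
        if not step.blocks <= resident:
            raise ScheduleIntegrityError(
                f"step {t}: blocks {set(step.blocks) - resident} not resident at execution"
            )
        total_loads += len(step.loads)
        if volume_p is not None:
            volume_p += sum(block_sizes[b] for b in step.loads)
        if volume_b is not None:
            volume_b += sum(block_bytes[b] for b in step.loads)
        trace.append(frozenset(resident))
    peak = max((len(r) for r in trace), default=0)
    return MemoryLedger(
        resident_trace=tuple(trace),
        peak_resident_blocks=peak,
        total_loads=total_loads,
        load_volume_proteins=volume_p,
        load_volume_bytes=volume_b,
    )


def _fmt_block(b: BlockId) -> str:
    return f"{b[0]}{b[1]}" if isinstance(b, tuple) else str(b)


def schedule_table(schedule: BlockPairSchedule) -> pd.DataFrame:
    """Tabulate a schedule (one row per step) for TSV export or inspection."""
    ledger = simulate_memory(schedule)
    rows = []
    for t, (step, resident) in enumerate(zip(schedule, ledger.resident_trace), start=1):
        rows.append(
            {
                "step": t,
                "i": step.i,
                "j": step.j,
                "loads": ",".join(sorted(_fmt_block(b) for b in step.loads)),
                "evicts": ",".join(sorted(_fmt_block(b) for b in step.evicts)),
                "resident_count": len(resident),
            }
        )
    return pd.DataFrame(
        rows, columns=["step", "i", "j", "loads", "evicts", "resident_count"]
    )
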