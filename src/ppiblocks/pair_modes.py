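"""Candidate-pair ingestion and per-mode pair enumeration.

Four inference modes share one pair vocabulary:

* ``all_pairs``  — every unordered pair of distinct proteins in a catalog;
* ``some_pairs`` — only an explicit candidate list (2-column TSV);
* ``sparse``     — some-pairs, but each block load is restricted to the
  proteins actually named by the current block pair's candidates;
* ``bipartite``  — every cross pair between two disjoint catalogs.

Pairs are canonically ordered: lower catalog position first within one
catalog, and set-A protein first across two catalogs (never re-ordered
across sets). Candidate pairs are bucketed once, up front, by the block
pair their members fall in — output-equivalent to checking each
enumerated pair against a membership matrix, without scanning the
unrequested pairs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

from .block_plan import BlockPartition, ProteinCatalog

logger = logging.getLogger("ppiblocks")

__all__ = [
    "MODES",
    "CandidatePairSet",
    "PairBuckets",
    "PairValidationError",
    "PairParseError",
    "canonical_pair",
    "read_pairs",
    "make_pair_set",
    "write_pairs",
    "bucket_pairs",
    "sparse_selection",
    "enumerate_step_pairs",
]

MODES = ("all_pairs", "some_pairs", "sparse", "bipartite")


class PairValidationError(ValueError):
    """Candidate pairs reference ids absent from the catalog(s)."""


class PairParseError(ValueError):
    """Malformed row in a pair-list file."""


def canonical_pair(u: str, v: str, catalog: ProteinCatalog) -> Tuple[str, str]:
    """Orient a within-catalog pair so the lower catalog position comes first."""
    return (u, v) if catalog.position(u) <= catalog.position(v) else (v, u)


@dataclass(frozen=True)
class CandidatePairSet:
    """Canonicalized, de-duplicated candidate pairs tied to their catalog(s).

    ``catalog_b`` is None for within-catalog pairs; when present, every
    pair is (set-A id, set-B id) and is never flipped.
    """

    pairs: frozenset
    catalog: ProteinCatalog
    catalog_b: Optional[ProteinCatalog] = None

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def bipartite(self) -> bool:
        return self.catalog_b is not None

    def sorted(self) -> list:
        """Pairs in canonical (catalog-position) order."""
        if self.bipartite:
            key = lambda p: (self.catalog.position(p[0]), self.catalog_b.position(p[1]))
        else:
            key = lambda p: (self.catalog.position(p[0]), self.catalog.position(p[1]))
        return sorted(self.pairs, key=key)


def make_pair_set(
    pairs: Iterable[Tuple[str, str]],
    catalog: ProteinCatalog,
    catalog_b: Optional[ProteinCatalog] = None,
    allow_self: bool = False,
) -> CandidatePairSet:
    """Canonicalize, validate and de-duplicate an in-memory pair collection."""
    unknown: list = []
    canon = set()
    n_raw = 0
    for u, v in pairs:
        n_raw += 1
        if catalog_b is None:
            bad = [x for x in (u, v) if x not in catalog.index]
            if bad:
                unknown.extend(bad)
                continue
            if u == v and not allow_self:
                raise PairValidationError(
                    f"self-pair ({u!r}, {v!r}) not allowed (allow_self=False)"
                )
            canon.add(canonical_pair(u, v, catalog))
        else:
            if u not in catalog.index:
                unknown.append(u)
            if v not in catalog_b.index:
                unknown.append(v)
            if u in catalog.index and v in catalog_b.index:
                canon.add((u, v))
    if unknown:
        uniq = sorted(set(unknown))
        raise PairValidationError(
            f"{len(uniq)} pair id(s) absent from catalog(s): {uniq[:10]}"
        )
    dropped = n_raw - len(canon)
    if dropped:
        logger.info("de-duplicated %d redundant candidate pair row(s)", dropped)
    return CandidatePairSet(pairs=frozenset(canon), catalog=catalog, catalog_b=catalog_b)


def read_pairs(
    path,
    catalog: ProteinCatalog,
    catalog_b: Optional[ProteinCatalog] = None,
    allow_self: bool = False,
) -> CandidatePairSet:
    """Read a 2-column TSV of candidate pairs (no header; '#' comments).

    Rows are canonicalized and silently de-duplicated (with a logged
    count); ids absent from the catalog(s) raise a validation error
    naming the offenders, and malformed rows raise with the line number.
    """
    raw = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise PairParseError(
                    f"{path}:{lineno}: expected 2 tab-separated ids, got {line!r}"
                )
            raw.append((fields[0].strip(), fields[1].strip()))
    return make_pair_set(raw, catalog, catalog_b=catalog_b, allow_self=allow_self)


def write_pairs(pairs: Iterable[Tuple[str, str]], path) -> None:
    """Write pairs as headerless 2-column TSV (fixture/export helper)."""
    with open(path, "w") as fh:
        for u, v in pairs:
            fh.write(f"{u}\t{v}\n")


@dataclass(frozen=True)
class PairBuckets:
    """Candidate pairs grouped by the normalized block pair of their members."""

    buckets: dict  # (i, j) -> list of id pairs
    bipartite: bool = False

    def get(self, block_pair) -> list:
        return self.buckets.get(tuple(block_pair), [])

    def __len__(self) -> int:
        return len(self.buckets)

    def total_pairs(self) -> int:
        return sum(len(v) for v in self.buckets.values())


def bucket_pairs(
    pair_set: CandidatePairSet,
    partition: BlockPartition,
    partition_b: Optional[BlockPartition] = None,
) -> PairBuckets:
    """Assign each candidate pair to the block pair of its members.

    Within one catalog a canonical pair (u, v) lands in
    (block(u), block(v)) which is already normalized i <= j because the
    partition is contiguous in catalog order. Bucket contents partition
    the candidate set exactly.
    """
    buckets: dict = {}
    if pair_set.bipartite:
        if partition_b is None:
            raise ValueError("bipartite pair set requires two partitions")
        cat_a, cat_b = pair_set.catalog, pair_set.catalog_b
        for u, v in pair_set:
            key = (
                partition.block_of(cat_a.position(u)),
                partition_b.block_of(cat_b.position(v)),
            )
            buckets.setdefault(key, []).append((u, v))
    else:
        cat = pair_set.catalog
        for u, v in pair_set:
            bu = partition.block_of(cat.position(u))
            bv = partition.block_of(cat.position(v))
            key = (bu, bv) if bu <= bv else (bv, bu)
            buckets.setdefault(key, []).append((u, v))
    for key in buckets:
        buckets[key].sort()
    return PairBuckets(buckets=buckets, bipartite=pair_set.bipartite)


def sparse_selection(buckets: PairBuckets, block_pair) -> Tuple[set, set]:
    """Proteins of each block actually needed by one block pair's candidates.

    Returns (selection for the first block, selection for the second);
    both empty when the bucket is absent, in which case the step can be
    skipped outright.
    """
    i, j = block_pair
    pairs = buckets.get((i, j))
    first: set = set()
    second: set = set()
    for u, v in pairs:
        first.add(u)
        second.add(v)
    if not buckets.bipartite and i == j:
        both = first | second
        return both, both
    return first, second


def enumerate_step_pairs(
    mode: str,
    step,
    catalog: ProteinCatalog,
    partition: BlockPartition,
    buckets: Optional[PairBuckets] = None,
    catalog_b: Optional[ProteinCatalog] = None,
    partition_b: Optional[BlockPartition] = None,
    include_self: bool = False,
) -> list:
    """Ordered pair tasks for one scheduled block-pair step.

    all_pairs: the full cross product for i < j and all unordered
    within-block pairs for i = j (self-pairs only when ``include_self``);
    some_pairs/sparse: exactly the bucket's candidates; bipartite: the
    full cross product of the two resident blocks. The union over a whole
    schedule covers every requested pair exactly once.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    i, j = step.i, step.j
    if mode == "all_pairs":
        if i == j:
            members = partition.members(i, catalog)
            tasks = list(itertools.combinations(members, 2))
            if include_self:
                tasks.extend((u, u) for u in members)
                tasks.sort(
                    key=lambda p: (catalog.position(p[0]), catalog.position(p[1]))
                )
            return tasks
        left = partition.members(i, catalog)
        right = partition.members(j, catalog)
        return [(u, v) for u in left for v in right]
    if mode in ("some_pairs", "sparse"):
        if buckets is None:
            raise ValueError(f"mode {mode!r} requires pair buckets")
        return list(buckets.get((i, j)))
    # bipartite
    if catalog_b is None or partition_b is None:
        raise ValueError("bipartite mode requires a second catalog and partition")
    left = partition.members(i, catalog)
    right = partition_b.members(j, catalog_b)
    return [(u, v) for u in left for v in right]
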