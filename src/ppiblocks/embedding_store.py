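"""Keyed per-protein embedding persistence and block-granular residency.

Embeddings live in a single HDF5 container with one 2-D float32 dataset
per protein id at the root — the conventional single-file keyed layout for
pre-computed protein-language-model embeddings. Each array has shape
(length, dim) with one row per residue.

Blocks of embeddings are loaded and evicted through a
:class:`MemoryAccountant`, which tracks live residency in blocks and
bytes and enforces the engine's three-resident-block bound at run time.
A synthetic store generator produces seeded random fixtures so nothing
external is ever required.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import h5py
import numpy as np
from Bio import SeqIO

from .block_plan import BlockPartition, ProteinCatalog

__all__ = [
    "EmbeddingRecord",
    "ResidentBlock",
    "MemoryAccountant",
    "MemoryBoundError",
    "MissingProteinError",
    "InvalidSelectionError",
    "BlockStateError",
    "EmbeddingStore",
    "open_store",
    "load_block",
    "evict_block",
    "generate_synthetic_store",
    "read_catalog_ids",
    "read_fasta_catalog",
    "catalog_from_store",
    "write_catalog",
]

BYTES_PER_VALUE = 4  # embeddings are stored and accounted as float32


class MissingProteinError(KeyError):
    """A requested protein id has no dataset in the store."""

    def __str__(self):  # KeyError quotes its arg; keep the message readable
        return self.args[0] if self.args else ""


class InvalidSelectionError(ValueError):
    """A sparse selection names proteins outside the requested block."""


class BlockStateError(RuntimeError):
    """Block residency operation applied in the wrong state (e.g. double evict)."""


class MemoryBoundError(RuntimeError):
    """Loading a block would exceed the configured resident-block bound."""


@dataclass(frozen=True)
class EmbeddingRecord:
    """One protein's embedding: a (length, dim) float32 matrix."""

    protein_id: str
    array: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.array, dtype=np.float32)
        if a.ndim != 2 or a.shape[0] < 1 or a.shape[1] < 1:
            raise ValueError(
                f"embedding for {self.protein_id!r} must be a non-empty 2-D "
                f"array, got shape {a.shape}"
            )
        object.__setattr__(self, "array", a)

    @property
    def length(self) -> int:
        return self.array.shape[0]

    @property
    def dim(self) -> int:
        return self.array.shape[1]

    @property
    def byte_size(self) -> int:
        return self.array.shape[0] * self.array.shape[1] * BYTES_PER_VALUE


@dataclass
class ResidentBlock:
    """A block's in-memory records: all of its proteins, or a sparse subset."""

    block_id: object
    records: dict  # protein_id -> EmbeddingRecord

    @property
    def byte_size(self) -> int:
        return sum(r.byte_size for r in self.records.values())

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.records

    def __getitem__(self, protein_id: str) -> EmbeddingRecord:
        try:
            return self.records[protein_id]
        except KeyError:
            raise MissingProteinError(
                f"protein {protein_id!r} not resident in block {self.block_id}"
            ) from None


class MemoryAccountant:
    """Live ledger of resident blocks with an optional hard residency bound.

    ``max_resident_blocks`` is the engine's min(B, 3) guarantee made
    executable: any load that would push residency past it aborts the run
    with a diagnostic instead of silently growing memory.
    """

    def __init__(self, max_resident_blocks: Optional[int] = None):
        self.max_resident_blocks = max_resident_blocks
        self._blocks: dict = {}
        self.peak_resident_blocks = 0
        self.peak_bytes = 0
        self.total_loads = 0
        self.total_bytes_loaded = 0
        self.total_proteins_loaded = 0

    @property
    def resident_blocks(self) -> tuple:
        return tuple(self._blocks)

    @property
    def resident_count(self) -> int:
        return len(self._blocks)

    @property
    def resident_bytes(self) -> int:
        return sum(b.byte_size for b in self._blocks.values())

    def register(self, block: ResidentBlock) -> None:
        if block.block_id in self._blocks:
            raise BlockStateError(f"block {block.block_id} is already resident")
        if (
            self.max_resident_blocks is not None
            and len(self._blocks) + 1 > self.max_resident_blocks
        ):
            raise MemoryBoundError(
                f"loading block {block.block_id} would make "
                f"{len(self._blocks) + 1} blocks resident "
                f"(bound is {self.max_resident_blocks}; resident: "
                f"{sorted(map(str, self._blocks))})"
            )
        self._blocks[block.block_id] = block
        self.total_loads += 1
        self.total_bytes_loaded += block.byte_size
        self.total_proteins_loaded += len(block.records)
        self.peak_resident_blocks = max(self.peak_resident_blocks, len(self._blocks))
        self.peak_bytes = max(self.peak_bytes, self.resident_bytes)

    def get(self, block_id) -> ResidentBlock:
        try:
            return self._blocks[block_id]
        except KeyError:
            raise BlockStateError(f"block {block_id} is not resident") from None

    def release(self, block_id) -> int:
        block = self.get(block_id)
        released = block.byte_size
        block.records.clear()
        del self._blocks[block_id]
        return released


class EmbeddingStore:
    """Read-only handle on a keyed HDF5 embedding container.

    Supports key listing and per-key retrieval without loading everything;
    usable as a context manager.
    """

    def __init__(self, path):
        if not os.path.exists(path):
            raise IOError(f"embedding store not found: {path}")
        try:
            self._h5 = h5py.File(path, "r")
        except OSError as e:
            raise IOError(f"not a readable HDF5 container: {path} ({e})") from e
        self.path = str(path)

    def keys(self) -> list:
        return list(self._h5.keys())

    def __len__(self) -> int:
        return len(self._h5)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._h5

    def get(self, protein_id: str) -> np.ndarray:
        if protein_id not in self._h5:
            raise MissingProteinError(
                f"protein {protein_id!r} not found in store {self.path}"
            )
        return np.asarray(self._h5[protein_id], dtype=np.float32)

    def length_of(self, protein_id: str) -> int:
        if protein_id not in self._h5:
            raise MissingProteinError(
                f"protein {protein_id!r} not found in store {self.path}"
            )
        return int(self._h5[protein_id].shape[0])

    def missing(self, ids: Iterable[str]) -> list:
        return [i for i in ids if i not in self._h5]

    def close(self) -> None:
        self._h5.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def open_store(path) -> EmbeddingStore:
    """Open a keyed HDF5 embedding container for reading."""
    return EmbeddingStore(path)


def load_block(
    store: EmbeddingStore,
    partition: BlockPartition,
    catalog: ProteinCatalog,
    block_index: int,
    selection: Optional[Iterable[str]] = None,
    accountant: Optional[MemoryAccountant] = None,
    block_id=None,
) -> ResidentBlock:
    """Load a block's embeddings (all proteins, or a sparse ``selection``).

    ``block_id`` overrides the residency-ledger identity of the block
    (bipartite runs tag blocks by catalog); it defaults to ``block_index``.
    Registers with ``accountant`` when one is given, which is where the
    residency bound is enforced.
    """
    members = partition.members(block_index, catalog)
    if selection is not None:
        selection = list(dict.fromkeys(selection))  # de-dup, keep order
        outside = [s for s in selection if s not in set(members)]
        if outside:
            raise InvalidSelectionError(
                f"selection names proteins outside block {block_index}: {outside}"
            )
        wanted = selection
    else:
        wanted = list(members)
    absent = store.missing(wanted)
    if absent:
        raise MissingProteinError(
            f"block {block_index}: proteins absent from store: {absent}"
        )
    records = {pid: EmbeddingRecord(pid, store.get(pid)) for pid in wanted}
    block = ResidentBlock(
        block_id=block_index if block_id is None else block_id, records=records
    )
    if accountant is not None:
        accountant.register(block)
    return block


def evict_block(accountant: MemoryAccountant, block_id) -> int:
    """Release a resident block's records; returns bytes released."""
    return accountant.release(block_id)


# ---------------------------------------------------------------------------
# Synthetic fixtures and catalog I/O
# ---------------------------------------------------------------------------


def generate_synthetic_store(
    ids: Sequence[str],
    length_range: tuple,
    dim: int,
    seed: int,
    path,
    overwrite: bool = False,
) -> dict:
    """Write a seeded random embedding store; returns {id: length}.

    Lengths are drawn uniformly from ``length_range`` (inclusive) and
    values are standard-normal float32. Identical seeds yield
    byte-identical arrays. Stands in for upstream protein-language-model
    embedding, which is out of scope here.
    """
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("protein ids must be unique")
    if dim < 1:
        raise ValueError(f"dim must be >= 1, got {dim}")
    lo, hi = int(length_range[0]), int(length_range[1])
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid length range: {length_range}")
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"refusing to overwrite existing store: {path}")
    rng = np.random.default_rng(seed)
    lengths = {}
    with h5py.File(path, "w") as h5:
        for pid in ids:
            length = int(rng.integers(lo, hi + 1))
            arr = rng.standard_normal((length, dim)).astype(np.float32)
            h5.create_dataset(pid, data=arr)
            lengths[pid] = length
    return lengths


def read_catalog_ids(path) -> list:
    """Read a plain-text catalog: one id per line, '#' comments ignored."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line.split()[0])
    return ids


def read_fasta_catalog(path, max_length: int = 1000) -> ProteinCatalog:
    """Build a catalog from FASTA, dropping sequences longer than ``max_length``.

    The 1000-residue default is the conventional cap for PPI inference on
    whole proteomes, where very long sequences dominate embedding memory.
    """
    ids, lengths = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) <= max_length:
            ids.append(rec.id)
            lengths.append(len(rec.seq))
    return ProteinCatalog(ids=tuple(ids), lengths=tuple(lengths))


def catalog_from_store(
    store: EmbeddingStore, ids: Optional[Sequence[str]] = None
) -> ProteinCatalog:
    """Build a catalog (ids in given or store order, lengths from shapes)."""
    ids = list(ids) if ids is not None else store.keys()
    absent = store.missing(ids)
    if absent:
        raise MissingProteinError(f"catalog proteins absent from store: {absent}")
    return ProteinCatalog(
        ids=tuple(ids), lengths=tuple(store.length_of(i) for i in ids)
    )


def write_catalog(ids: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        for pid in ids:
            fh.write(f"{pid}\n")
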