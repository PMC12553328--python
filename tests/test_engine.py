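"""Engine correctness: mock scorer, serial oracle, blocked multi-worker runs.

The serial reference (preload everything, one process, canonical order)
is the oracle; every blocked/parallel configuration must reproduce its
output record set bit-for-bit at the written 6-decimal precision.
"""

import math
import os

import numpy as np
import pytest

from ppiblocks import (
    EngineConfig,
    MockScorer,
    PredictionRecord,
    ProteinCatalog,
    ScorerError,
    WorkerError,
    make_pair_set,
    open_store,
    read_predictions,
    run,
    score_pair,
    serial_reference,
    write_predictions,
)
from ppiblocks.embedding_store import EmbeddingRecord


def record_set(records):
    return {(r.id1, r.id2, f"{r.score:.6f}") for r in records}


class TestMockScorer:
    def test_zero_arrays_give_half(self):
        s = MockScorer()
        a = np.zeros((5, 4), dtype=np.float32)
        assert s.score(a, a) == pytest.approx(0.5)

    def test_unit_means_give_logistic_of_two(self):
        s = MockScorer()
        a = np.ones((3, 2), dtype=np.float32)
        b = np.ones((7, 2), dtype=np.float32)
        assert s.score(a, b) == pytest.approx(1 / (1 + math.exp(-2)))

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((6, 4)).astype(np.float32)
        b = rng.standard_normal((9, 4)).astype(np.float32)
        s = MockScorer()
        assert s.score(a, b) == s.score(b, a)

    def test_dim_mismatch(self):
        s = MockScorer(dim=4)
        good = np.zeros((3, 4), dtype=np.float32)
        bad = np.zeros((3, 5), dtype=np.float32)
        with pytest.raises(ScorerError):
            s.score(good, bad)
        with pytest.raises(ScorerError):
            MockScorer().score(good, np.zeros((0, 4), dtype=np.float32))

    def test_score_pair_wrapper(self):
        r = EmbeddingRecord("p", np.zeros((2, 2)))
        assert score_pair(MockScorer(), r, r) == pytest.approx(0.5)


class TestSerialReference:
    def test_all_pairs_canonical_order(self, make_fixture):
        catalog, path = make_fixture(n=4)
        with open_store(path) as store:
            recs = serial_reference(catalog, store, MockScorer())
        assert len(recs) == 6
        ids = catalog.ids
        assert [(r.id1, r.id2) for r in recs] == [
            (ids[a], ids[b]) for a in range(4) for b in range(a + 1, 4)
        ]
        assert all(0 < r.score < 1 for r in recs)

    def test_empty_candidate_set(self, make_fixture):
        catalog, path = make_fixture(n=4)
        ps = make_pair_set([], catalog)
        with open_store(path) as store:
            assert serial_reference(catalog, store, MockScorer(), pairs=ps) == []


class TestBlockedRun:
    @pytest.mark.parametrize("n_blocks", [1, 2, 3, 5])
    @pytest.mark.parametrize("n_workers", [1, 2, 4])
    def test_output_set_equals_serial_reference(
        self, make_fixture, tmp_path, n_blocks, n_workers
    ):
        catalog, path = make_fixture(n=20, seed=5)
        with open_store(path) as store:
            oracle = serial_reference(catalog, store, MockScorer())
        config = EngineConfig(
            mode="all_pairs", n_blocks=n_blocks, n_workers=n_workers,
            output_prefix=str(tmp_path / f"out_{n_blocks}_{n_workers}"),
        )
        summary = run(config, catalog, path, MockScorer())
        got = read_predictions(summary.output_path)
        assert record_set(got) == record_set(oracle)
        # exactly-once: no duplicate id pairs
        assert len({(r.id1, r.id2) for r in got}) == len(got) == 190
        assert summary.pairs_scored == summary.pairs_requested == 190
        assert summary.peak_resident_blocks <= min(n_blocks, 3)

    def test_some_pairs_exact_records(self, make_fixture, tmp_path):
        catalog, path = make_fixture(n=10)
        ps = make_pair_set(
            [(catalog.ids[0], catalog.ids[7]),
             (catalog.ids[2], catalog.ids[3]),
             (catalog.ids[8], catalog.ids[9])],
            catalog,
        )
        config = EngineConfig(
            mode="some_pairs", n_blocks=3, n_workers=2,
            output_prefix=str(tmp_path / "some"),
        )
        summary = run(config, catalog, path, MockScorer(), pairs=ps)
        got = read_predictions(summary.output_path)
        assert len(got) == 3
        assert {(r.id1, r.id2) for r in got} == ps.pairs

    @pytest.mark.parametrize("mode", ["some_pairs", "sparse"])
    def test_candidate_modes_match_serial(self, make_fixture, tmp_path, mode):
        catalog, path = make_fixture(n=15, seed=2)
        ids = catalog.ids
        pairs = [
            (ids[a], ids[b])
            for a in range(15)
            for b in range(a + 1, 15)
            if (a * 15 + b) % 3 == 0
        ]
        ps = make_pair_set(pairs, catalog)
        with open_store(path) as store:
            oracle = serial_reference(catalog, store, MockScorer(), pairs=ps)
        config = EngineConfig(
            mode=mode, n_blocks=4, n_workers=2,
            output_prefix=str(tmp_path / mode),
        )
        summary = run(config, catalog, path, MockScorer(), pairs=ps)
        assert record_set(read_predictions(summary.output_path)) == record_set(oracle)
        assert summary.pairs_scored == len(ps)

    def test_bipartite_matches_serial_and_shared_store(
        self, make_fixture, tmp_path
    ):
        catalog, path = make_fixture(n=12, seed=9)
        cat_a = ProteinCatalog(catalog.ids[:5], catalog.lengths[:5])
        cat_b = ProteinCatalog(catalog.ids[5:], catalog.lengths[5:])
        with open_store(path) as store:
            oracle = serial_reference(
                cat_a, store, MockScorer(), catalog_b=cat_b, store_b=store
            )
        config = EngineConfig(
            mode="bipartite", n_blocks=2, n_blocks_b=3, n_workers=2,
            output_prefix=str(tmp_path / "bip"),
        )
        summary = run(config, cat_a, path, MockScorer(), catalog_b=cat_b)
        got = read_predictions(summary.output_path)
        assert record_set(got) == record_set(oracle)
        assert summary.pairs_scored == 5 * 7
        assert summary.peak_resident_blocks <= 3
        # explicit second store path gives the identical record set
        config2 = EngineConfig(
            mode="bipartite", n_blocks=2, n_blocks_b=3, n_workers=2,
            output_prefix=str(tmp_path / "bip2"),
        )
        summary2 = run(
            config2, cat_a, path, MockScorer(), catalog_b=cat_b, store_path_b=path
        )
        assert record_set(read_predictions(summary2.output_path)) == record_set(got)

    def test_sparse_skips_unneeded_blocks(self, make_fixture, tmp_path):
        catalog, path = make_fixture(n=12)
        ps = make_pair_set([(catalog.ids[0], catalog.ids[1])], catalog)
        config = EngineConfig(
            mode="sparse", n_blocks=6, n_workers=1,
            output_prefix=str(tmp_path / "sp"),
        )
        summary = run(config, catalog, path, MockScorer(), pairs=ps)
        assert summary.pairs_scored == 1
        # only the single diagonal block pair is touched, with 2 proteins
        assert summary.total_loads == 1
        assert summary.peak_resident_blocks == 1

    def test_threshold_above_any_score(self, make_fixture, tmp_path):
        catalog, path = make_fixture(n=6)
        config = EngineConfig(
            mode="all_pairs", n_blocks=2, n_workers=1, threshold=1.1,
            output_prefix=str(tmp_path / "hi"),
        )
        summary = run(config, catalog, path, MockScorer())
        assert summary.positives == 0
        assert len(read_predictions(summary.positive_path)) == 0
        assert len(read_predictions(summary.output_path)) == 15

    def test_threshold_zero_makes_positives_equal_full(self, make_fixture, tmp_path):
        catalog, path = make_fixture(n=6)
        config = EngineConfig(
            mode="all_pairs", n_blocks=2, n_workers=2, threshold=0.0,
            output_prefix=str(tmp_path / "lo"),
        )
        summary = run(config, catalog, path, MockScorer())
        full = read_predictions(summary.output_path)
        pos = read_predictions(summary.positive_path)
        assert record_set(full) == record_set(pos)

    def test_sorted_output_flag(self, make_fixture, tmp_path):
        catalog, path = make_fixture(n=10)
        config = EngineConfig(
            mode="all_pairs", n_blocks=3, n_workers=3, sorted_output=True,
            output_prefix=str(tmp_path / "sorted"),
        )
        summary = run(config, catalog, path, MockScorer())
        got = read_predictions(summary.output_path)
        keys = [(catalog.position(r.id1), catalog.position(r.id2)) for r in got]
        assert keys == sorted(keys)

    def test_no_torn_rows_under_many_workers(self, make_fixture, tmp_path):
        catalog, path = make_fixture(n=16)
        config = EngineConfig(
            mode="all_pairs", n_blocks=4, n_workers=4, chunk_size=7,
            output_prefix=str(tmp_path / "many"),
        )
        summary = run(config, catalog, path, MockScorer())
        with open(summary.output_path) as fh:
            lines = fh.read().splitlines()
        assert lines[0] == "id1\tid2\tscore"
        assert all(len(line.split("\t")) == 3 for line in lines[1:])
        assert len(lines) - 1 == 120

    def test_missing_embedding_fails_before_scoring(
        self, make_fixture, tmp_path
    ):
        catalog, path = make_fixture(n=4)
        bigger = ProteinCatalog(
            catalog.ids + ("ghost",), catalog.lengths + (10,)
        )
        config = EngineConfig(
            mode="all_pairs", n_blocks=2, n_workers=1,
            output_prefix=str(tmp_path / "miss"),
        )
        with pytest.raises(KeyError, match="ghost"):
            run(config, bigger, path, MockScorer())
        # validation failure precedes any output
        assert not os.path.exists(tmp_path / "miss.tsv")

    def test_worker_failure_aborts_run(self, make_fixture, tmp_path):
        catalog, path = make_fixture(n=6)
        config = EngineConfig(
            mode="all_pairs", n_blocks=2, n_workers=2,
            output_prefix=str(tmp_path / "fail"),
        )
        with pytest.raises(WorkerError):
            run(config, catalog, path, MockScorer(dim=999))

    def test_run_summary_log_file(self, make_fixture, tmp_path):
        catalog, path = make_fixture(n=6)
        prefix = str(tmp_path / "logged")
        config = EngineConfig(
            mode="all_pairs", n_blocks=3, n_workers=1, output_prefix=prefix
        )
        run(config, catalog, path, MockScorer())
        log = open(f"{prefix}.log").read()
        assert "pairs_scored\t15" in log
        assert "peak_resident_blocks\t3" in log
        assert "total_block_loads\t3" in log


class TestWritePredictions:
    def test_counts_against_threshold(self, tmp_path):
        rng = np.random.default_rng(1)
        records = [
            PredictionRecord(f"a{i}", f"b{i}", float(s))
            for i, s in enumerate(rng.uniform(size=15))
        ]
        expected_pos = sum(1 for r in records if r.score >= 0.5)
        prefix = str(tmp_path / "w")
        n, n_pos = write_predictions(records, 0.5, prefix)
        assert (n, n_pos) == (15, expected_pos)
        assert len(read_predictions(f"{prefix}.tsv")) == 15
        assert len(read_predictions(f"{prefix}.positive.tsv")) == expected_pos

    def test_zero_records(self, tmp_path):
        prefix = str(tmp_path / "empty")
        assert write_predictions([], 0.5, prefix) == (0, 0)
        for suffix in (".tsv", ".positive.tsv"):
            with open(f"{prefix}{suffix}") as fh:
                assert fh.read() == "id1\tid2\tscore\n"

    def test_unwritable_destination(self, tmp_path):
        with pytest.raises(OSError):
            write_predictions([], 0.5, str(tmp_path / "no" / "such" / "dir" / "x"))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(mode="nope"),
            dict(n_blocks=0),
            dict(n_workers=0),
            dict(threshold=-0.1),
            dict(buffer_capacity=0),
            dict(chunk_size=0),
        ],
    )
    def test_rejects_bad_config(self, kwargs):
        with pytest.raises(ValueError):
            EngineConfig(**kwargs)

    def test_candidate_modes_require_pairs(self, make_fixture, tmp_path):
        catalog, path = make_fixture(n=4)
        config = EngineConfig(
            mode="some_pairs", output_prefix=str(tmp_path / "x")
        )
        with pytest.raises(ValueError):
            run(config, catalog, path, MockScorer())
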