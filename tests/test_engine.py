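import itertools

import numpy as np
import pytest

from lingo_mcc import (
    Compound,
    EngineConfig,
    SynthSpec,
    compare_a2a,
    compare_o2a,
    gen_library,
    report_hits,
    screen,
    tanimoto_oracle,
)
from lingo_mcc.engine import RunStats
from lingo_mcc.errors import ConfigurationError


@pytest.fixture(scope="module")
def libraries():
    q = gen_library(SynthSpec(n=20, params=(10, 60), seed=11))
    d = gen_library(SynthSpec(n=30, params=(10, 60), seed=12))
    return q, d


class TestCompare:
    def test_self_comparison_symmetric_unit_diagonal(self, tiny_library):
        m = compare_a2a(tiny_library, tiny_library)
        assert np.allclose(np.diag(m.values), 1.0)
        assert np.array_equal(m.values, m.values.T)
        assert m.query_ids == m.db_ids

    def test_o2a_row_equals_a2a_row(self, libraries):
        query, db = libraries
        full = compare_a2a(query, db)
        row = compare_o2a(query[3], db)
        assert row.shape == (1, len(db))
        assert np.array_equal(row.values[0], full.values[3])

    @pytest.mark.parametrize("mode", ["multiset", "set"])
    def test_every_entry_matches_string_oracle(self, libraries, mode):
        query, db = libraries
        m = compare_a2a(query, db, EngineConfig(mode=mode))
        for i, qc in enumerate(query):
            for j, dc in enumerate(db):
                expected = tanimoto_oracle(qc.smiles, dc.smiles, 4, mode)
                assert m.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_worker_count_never_changes_values(self, libraries):
        query, db = libraries
        reference = compare_a2a(query, db, EngineConfig(n_workers=1))
        for n in (2, 4):
            m = compare_a2a(query, db, EngineConfig(n_workers=n))
            assert np.array_equal(m.values, reference.values)

    def test_strategy_and_policy_never_change_values(self, libraries):
        query, db = libraries
        reference = compare_a2a(query, db)
        for strategy, policy in itertools.product("SNLM", ["greedy_lpt", "sorted_round_robin"]):
            cfg = EngineConfig(strategy=strategy, policy=policy, n_workers=3)
            m = compare_a2a(query, db, cfg)
            assert np.array_equal(m.values, reference.values)

    def test_empty_inputs_rejected(self, tiny_library):
        with pytest.raises(ConfigurationError):
            compare_a2a([], tiny_library)
        with pytest.raises(ConfigurationError):
            compare_a2a(tiny_library, [])

    def test_pair_count_doubles_with_database_size(self, libraries):
        query, db = libraries
        s1, s2 = RunStats(), RunStats()
        compare_a2a(query, db, stats=s1)
        compare_a2a(query, db + db_shifted(db), stats=s2)
        assert s1.pair_count == len(query) * len(db)
        assert s2.pair_count == 2 * s1.pair_count

    def test_stats_capture_worker_loads_and_timings(self, libraries):
        query, db = libraries
        stats = RunStats()
        compare_a2a(query, db, EngineConfig(n_workers=3), stats)
        assert len(stats.worker_loads) == 3
        assert stats.imbalance >= 1.0
        assert set(stats.timings) == {"preprocess", "compare"}


def db_shifted(db):
    return [Compound(id=c.id + "b", smiles=c.smiles, source_line=c.source_line) for c in db]


class TestReportHits:
    def test_matches_brute_force_filter(self, libraries):
        query, db = libraries
        m = compare_a2a(query, db)
        threshold = 0.05
        hits = report_hits(m, threshold)
        expected = {
            (qc.id, dc.id)
            for i, qc in enumerate(query)
            for j, dc in enumerate(db)
            if m.values[i, j] > threshold
        }
        assert {(q, d) for q, d, _ in hits} == expected

    def test_threshold_is_strict(self):
        # 17 shared Lingos out of a 20-Lingo union: coefficient exactly 17/20
        a, b = Compound("a", "C" * 20), Compound("b", "C" * 23)
        m = compare_a2a([a], [b])
        assert m.values[0, 0] == 17 / 20 == 0.85
        assert report_hits(m, 0.85) == []
        assert report_hits(m, 0.849) == [("a", "b", 0.85)]

    def test_threshold_one_excludes_even_identical_compounds(self, tiny_library):
        m = compare_a2a(tiny_library, tiny_library)
        assert report_hits(m, 1.0) == []

    def test_ordering_query_then_descending_coefficient_then_db_id(self, libraries):
        query, db = libraries
        hits = report_hits(compare_a2a(query, db), 0.0)
        qorder = {c.id: i for i, c in enumerate(query)}
        keys = [(qorder[q], -c, d) for q, d, c in hits]
        assert keys == sorted(keys)


class TestScreen:
    def test_equals_matrix_route(self, libraries):
        query, db = libraries
        cfg = EngineConfig(threshold=0.05)
        expected = report_hits(compare_a2a(query, db, cfg), cfg.threshold)
        assert screen(query, db, cfg) == expected

    @pytest.mark.parametrize("chunk", [1, 7, 30, 100])
    def test_database_tiling_does_not_change_hits(self, libraries, chunk):
        query, db = libraries
        cfg = EngineConfig(threshold=0.05, chunk_size=chunk)
        whole = screen(query, db, EngineConfig(threshold=0.05))
        assert screen(query, db, cfg) == whole


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"q": 0},
            {"mode": "cosine"},
            {"strategy": "Z"},
            {"policy": "random"},
            {"n_workers": 0},
            {"threshold": 1.5},
            {"chunk_size": 0},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            EngineConfig(**kwargs)
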