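"""Three-phase comparison engine: preprocess, compare in parallel, report.

*Preprocessing* builds every profile once.  The *comparison phase* splits the
**query** library across an abstract pool of workers according to the
configured workload strategy and partition policy (the stand-in for dividing
work over thread blocks and GPU cards by their computing capability); each
worker fills its own rows of the k × r coefficient matrix, and the rows merge
back in original query order, so the result is bit-identical for any worker
count, strategy or policy.  The *output phase* filters entries strictly
greater than the threshold (0.85 by default — "more than", so an entry at
exactly the threshold is excluded, even the 1.0 self-coefficient at
threshold 1.0).

Database profiles are shared by every worker; for memory-bounded operation
:func:`screen` tiles over database chunks and streams hits instead of
materializing the full matrix.
"""

from __future__ import annotations

import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels, scheduler
from .errors import ConfigurationError
from .lingo_core import DEFAULT_Q, LingoProfile, build_profile
from .smiles_io import Compound

__all__ = [
    "EngineConfig",
    "SimilarityMatrix",
    "RunStats",
    "compare_a2a",
    "compare_o2a",
    "report_hits",
    "screen",
]

Hit = tuple[str, str, float]


@dataclass(frozen=True)
class EngineConfig:
    """Resolved knobs for one engine run.

    ``seed`` is carried for synthetic-library generation only; the engine
    itself is fully deterministic.
    """

    q: int = DEFAULT_Q
    mode: str = "multiset"
    strategy: str = "M"
    policy: str = "greedy_lpt"
    n_workers: int = 1
    worker_weights: tuple[float, ...] | None = None
    threshold: float = 0.85
    ring_digit_zeroing: bool = False
    chunk_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.q < 1:
            raise ConfigurationError(f"q must be >= 1, got {self.q}")
        if self.mode not in ("multiset", "set"):
            raise ConfigurationError(f"unknown similarity mode {self.mode!r}")
        if self.strategy not in scheduler.STRATEGIES:
            raise ConfigurationError(f"unknown workload strategy {self.strategy!r}")
        if self.policy not in scheduler.POLICIES:
            raise ConfigurationError(f"unknown partition policy {self.policy!r}")
        if self.n_workers < 1:
            raise ConfigurationError(f"n_workers must be >= 1, got {self.n_workers}")
        if not 0.0 <= self.threshold <= 1.0:
            raise ConfigurationError(f"threshold must be in [0, 1], got {self.threshold}")
        if self.chunk_size is not None and self.chunk_size < 1:
            raise ConfigurationError(f"chunk_size must be >= 1, got {self.chunk_size}")


@dataclass(frozen=True)
class SimilarityMatrix:
    """k × r Tanimoto coefficients with aligned identifier lists."""

    values: np.ndarray
    query_ids: tuple[str, ...]
    db_ids: tuple[str, ...]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class RunStats:
    """Instrumentation for one comparison run."""

    pair_count: int = 0
    worker_loads: list[float] = field(default_factory=list)
    imbalance: float = 0.0
    timings: dict[str, float] = field(default_factory=dict)


def _build_profiles(compounds: Sequence[Compound], config: EngineConfig) -> list[LingoProfile]:
    return [build_profile(c, q=config.q, ring_digit_zeroing=config.ring_digit_zeroing) for c in compounds]


def compare_a2a(
    query: Sequence[Compound],
    db: Sequence[Compound],
    config: EngineConfig | None = None,
    stats: RunStats | None = None,
) -> SimilarityMatrix:
    """All-to-all comparison: every query compound against every database compound.

    Pass a :class:`RunStats` to collect the instrumented pair count,
    per-worker loads and per-phase wall times.
    """
    config = config or EngineConfig()
    if len(query) == 0 or len(db) == 0:
        raise ConfigurationError("query and database must both be non-empty")

    t0 = time.perf_counter()
    q_profiles = _build_profiles(query, config)
    d_profiles = _build_profiles(db, config)
    qs, qn, qoff, qtot = _kernels.pack_csr(q_profiles)
    ds, dn, doff, dtot = _kernels.pack_csr(d_profiles)
    t1 = time.perf_counter()

    workloads = [scheduler.workload(p, config.strategy) for p in q_profiles]
    part = scheduler.partition(workloads, config.n_workers, config.worker_weights, config.policy)

    k, r = len(query), len(db)
    out = np.zeros((k, r), dtype=np.float64)
    mode = _kernels.MODE_MULTISET if config.mode == "multiset" else _kernels.MODE_SET

    def run_worker(indices: tuple[int, ...]) -> None:
        if indices:
            rows = np.asarray(indices, dtype=np.int64)
            _kernels.pairwise_rows(rows, qs, qn, qoff, qtot, ds, dn, doff, dtot, mode, out)

    if config.n_workers == 1:
        run_worker(part.assignments[0])
    else:
        with ThreadPoolExecutor(max_workers=config.n_workers) as pool:
            for fut in [pool.submit(run_worker, a) for a in part.assignments]:
                fut.result()
    t2 = time.perf_counter()

    if stats is not None:
        stats.pair_count += k * r
        stats.worker_loads = part.loads(workloads)
        stats.imbalance = scheduler.imbalance(part, workloads)
        stats.timings["preprocess"] = stats.timings.get("preprocess", 0.0) + (t1 - t0)
        stats.timings["compare"] = stats.timings.get("compare", 0.0) + (t2 - t1)

    return SimilarityMatrix(
        values=out,
        query_ids=tuple(c.id for c in query),
        db_ids=tuple(c.id for c in db),
    )


def compare_o2a(
    query: Compound,
    db: Sequence[Compound],
    config: EngineConfig | None = None,
    stats: RunStats | None = None,
) -> SimilarityMatrix:
    """One-to-all comparison: a single query compound against a library."""
    return compare_a2a([query], db, config, stats)


def report_hits(matrix: SimilarityMatrix, threshold: float = 0.85) -> list[Hit]:
    """Entries strictly greater than the threshold.

    Ordered by query (matrix row order), then descending coefficient, then
    database id ascending.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ConfigurationError(f"threshold must be in [0, 1], got {threshold}")
    rows, cols = np.nonzero(matrix.values > threshold)
    entries = [
        (i, float(matrix.values[i, j]), matrix.db_ids[j])
        for i, j in zip(rows.tolist(), cols.tolist())
    ]
    entries.sort(key=lambda e: (e[0], -e[1], e[2]))
    return [(matrix.query_ids[i], dbid, coef) for i, coef, dbid in entries]


def screen(
    query: Sequence[Compound],
    db: Sequence[Compound],
    config: EngineConfig | None = None,
    stats: RunStats | None = None,
) -> list[Hit]:
    """End-to-end screening that streams hits instead of keeping k × r floats.

    Tiles the database in chunks of ``config.chunk_size`` columns (one chunk
    covering the whole database when unset), filters each block at the
    configured threshold, and merges the per-block partial results into the
    report order of :func:`report_hits`.  Output is identical to
    ``report_hits(compare_a2a(...), threshold)``.
    """
    config = config or EngineConfig()
    if len(query) == 0 or len(db) == 0:
        raise ConfigurationError("query and database must both be non-empty")
    chunk = config.chunk_size or len(db)
    hits: list[Hit] = []
    for start in range(0, len(db), chunk):
        block = compare_a2a(query, db[start : start + chunk], config, stats)
        hits.extend(report_hits(block, config.threshold))
    qorder = {c.id: i for i, c in enumerate(query)}
    hits.sort(key=lambda h: (qorder[h[0]], -h[2], h[1]))
    return hits
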