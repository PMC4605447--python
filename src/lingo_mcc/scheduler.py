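"""Workload estimation and partitioning of compounds across workers.

The cost of comparing one compound against a library scales with the size of
its profile, so any of four profile-derived numbers can stand in for the cost
of a compound:

* ``S`` — sum of its unique Lingo scores,
* ``N`` — sum of its Lingo numbers (``= length − q + 1`` when length ≥ q),
* ``L`` — its character count,
* ``M`` — its magnitude (distinct-Lingo count).

N and L differ by the constant q − 1 for every compound long enough to have
Lingos, so they induce the same ordering — which is why strategy choice
barely matters in practice.  Two deterministic assignment policies map the
estimated workloads onto workers (stand-ins for thread blocks or GPU cards
with relative capability weights): cyclic dealing over the sorted list, and
greedy longest-processing-time-first (LPT).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .lingo_core import LingoProfile

__all__ = ["STRATEGIES", "POLICIES", "Partition", "workload", "partition", "imbalance"]

STRATEGIES = ("S", "N", "L", "M")
POLICIES = ("greedy_lpt", "sorted_round_robin")


def workload(profile: LingoProfile, strategy: str = "M") -> int:
    """Estimated comparison cost of one compound under a strategy.

    An empty profile costs 0 under S, N and M; L is the raw character count
    regardless (a 2-character SMILES still has length 2).
    """
    if strategy == "S":
        return int(profile.scores.astype(np.uint64).sum())
    if strategy == "N":
        return profile.total
    if strategy == "L":
        return profile.length
    if strategy == "M":
        return profile.magnitude
    raise ConfigurationError(f"strategy must be one of {STRATEGIES}, got {strategy!r}")


@dataclass(frozen=True)
class Partition:
    """Disjoint assignment of compound indices to workers."""

    assignments: tuple[tuple[int, ...], ...]
    worker_weights: tuple[float, ...]

    @property
    def n_workers(self) -> int:
        return len(self.assignments)

    def loads(self, workloads: Sequence[float]) -> list[float]:
        """Total assigned workload per worker."""
        return [sum(workloads[i] for i in idx) for idx in self.assignments]


def _check_weights(n_workers: int, worker_weights: Sequence[float] | None) -> list[float]:
    if n_workers < 1:
        raise ConfigurationError(f"n_workers must be >= 1, got {n_workers}")
    if worker_weights is None:
        return [1.0] * n_workers
    weights = [float(w) for w in worker_weights]
    if len(weights) != n_workers:
        raise ConfigurationError(
            f"{len(weights)} weights for {n_workers} workers"
        )
    if any(w <= 0 for w in weights):
        raise ConfigurationError("worker weights must be positive")
    return weights


def partition(
    workloads: Sequence[float],
    n_workers: int,
    worker_weights: Sequence[float] | None = None,
    policy: str = "greedy_lpt",
) -> Partition:
    """Assign compound indices to workers, balancing estimated cost.

    Indices are first sorted by workload descending (ties: lower index
    first).  ``greedy_lpt`` then assigns each index to the worker minimizing
    the projected weighted load ``(load + w) / weight`` (ties: lower worker
    number); ``sorted_round_robin`` deals the sorted indices cyclically,
    ignoring weights — the analogue of mapping a sorted library onto the
    threads of a block.  Both are deterministic.
    """
    weights = _check_weights(n_workers, worker_weights)
    if policy not in POLICIES:
        raise ConfigurationError(f"policy must be one of {POLICIES}, got {policy!r}")
    order = sorted(range(len(workloads)), key=lambda i: (-workloads[i], i))
    assignments: list[list[int]] = [[] for _ in range(n_workers)]
    if policy == "sorted_round_robin":
        for pos, idx in enumerate(order):
            assignments[pos % n_workers].append(idx)
    else:
        loads = [0.0] * n_workers
        for idx in order:
            w = workloads[idx]
            best = min(range(n_workers), key=lambda j: ((loads[j] + w) / weights[j], j))
            assignments[best].append(idx)
            loads[best] += w
    return Partition(
        assignments=tuple(tuple(a) for a in assignments),
        worker_weights=tuple(weights),
    )


def imbalance(part: Partition, workloads: Sequence[float]) -> float:
    """Max weighted worker load over the weighted mean load (1.0 = perfect).

    Returns 0.0 when the total workload is 0.
    """
    loads = part.loads(workloads)
    total = sum(loads)
    if total == 0:
        return 0.0
    total_weight = sum(part.worker_weights)
    mean = total / total_weight
    return max(l / w for l, w in zip(loads, part.worker_weights)) / mean
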