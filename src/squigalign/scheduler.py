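"""Batching, memory-budget and read-length load-balancing policies.

Nanopore read lengths are highly non-uniform (hundreds of bases to over
a megabase), which wrecks naive data-parallel execution: a batch is as
slow as its longest read, and per-read allocation cost dominates when
memory is claimed dynamically. The policies here are the
hardware-independent core of the remedy: pre-size a batch from a memory
budget and the expected events-per-base ratio, and partition reads into
a bulk *fast lane*, a *slow lane* for very long reads, and an *overflow*
lane for ultra-long reads (>100 kb) that are processed singly. How the
lanes are executed (threads, GPU, plain loop) is an executor detail;
:func:`run_batch` fixes the contract that lane choice never changes
numerical results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

from .abea import count_bands

__all__ = [
    "ReadClass",
    "SchedulerConfig",
    "LaneAssignment",
    "BatchResult",
    "classify_read",
    "estimated_cells",
    "plan_batch",
    "run_batch",
]


class ReadClass(Enum):
    NORMAL = "normal"
    VERY_LONG = "very_long"
    ULTRA_LONG = "ultra_long"


@dataclass(frozen=True)
class SchedulerConfig:
    """Knobs of the batching policy.

    ``memory_budget`` caps the estimated band-chain bytes of a batch.
    ``avg_events_per_base`` is the heuristic events/base ratio used to
    predict table sizes before events exist (about 2 for DNA);
    ``bytes_per_cell`` is what the aligner actually stores per band cell
    (8-byte score + 1-byte trace tag).
    """

    very_long_threshold: int = 30_000
    ultra_long_threshold: int = 100_000
    memory_budget: int = 512 * 1024 * 1024
    avg_events_per_base: float = 2.0
    bytes_per_cell: int = 9
    band_width: int = 100
    k: int = 6

    def __post_init__(self) -> None:
        if self.very_long_threshold >= self.ultra_long_threshold:
            raise ValueError("very_long_threshold must be < ultra_long_threshold")
        if self.memory_budget <= 0:
            raise ValueError("memory_budget must be > 0")
        if self.avg_events_per_base <= 0:
            raise ValueError("avg_events_per_base must be > 0")


@dataclass
class LaneAssignment:
    """Partition of a batch into execution lanes (disjoint, exhaustive)."""

    fast_lane: list = field(default_factory=list)
    slow_lane: list = field(default_factory=list)
    overflow: list = field(default_factory=list)

    def all_ids(self) -> list:
        return self.fast_lane + self.slow_lane + self.overflow


@dataclass
class BatchResult:
    """Per-read alignment results and recorded failures of one batch."""

    results: dict
    failures: dict


def classify_read(length: int, cfg: SchedulerConfig) -> ReadClass:
    """Length class of a read (strict thresholds: exactly at a cutoff
    stays in the lower class)."""
    if length < 0:
        raise ValueError("read length must be >= 0")
    if length > cfg.ultra_long_threshold:
        return ReadClass.ULTRA_LONG
    if length > cfg.very_long_threshold:
        return ReadClass.VERY_LONG
    return ReadClass.NORMAL


def estimated_cells(length: int, cfg: SchedulerConfig) -> int:
    """Predicted band-chain size (cells) for a read of given length.

    Uses the band chain's actual working set — W cells per band over
    ``count_bands`` anti-diagonals — with the event count predicted from
    ``avg_events_per_base``.
    """
    n_events = max(1, math.ceil(cfg.avg_events_per_base * length))
    n_kmers = max(1, length - cfg.k + 1)
    return cfg.band_width * count_bands(n_events, n_kmers)


def _normalise(read_lengths):
    items = []
    for idx, entry in enumerate(read_lengths):
        if isinstance(entry, (tuple, list)):
            rid, length = entry
        else:
            rid, length = idx, entry
        items.append((rid, int(length)))
    return items


def plan_batch(read_lengths, cfg: SchedulerConfig) -> tuple[list, LaneAssignment]:
    """Admit reads into a batch under the memory budget and assign lanes.

    Reads are admitted greedily in input order while the cumulative
    estimated band-chain bytes stay within ``cfg.memory_budget``;
    admission stops at the first read that does not fit. A single read
    exceeding the whole budget on its own is still admitted, alone, to
    the overflow lane (it must be processed somehow). Admitted reads are
    assigned to lanes by :func:`classify_read`.

    Parameters
    ----------
    read_lengths : sequence of int or of (read_id, length)
        Plain lengths use their position as read id.

    Returns
    -------
    (list of read ids, LaneAssignment)
    """
    items = _normalise(read_lengths)
    if not items:
        raise ValueError("empty read list")

    first_id, first_len = items[0]
    first_cost = estimated_cells(first_len, cfg) * cfg.bytes_per_cell
    if first_cost > cfg.memory_budget:
        return [first_id], LaneAssignment(overflow=[first_id])

    batch = []
    total = 0
    for rid, length in items:
        cost = estimated_cells(length, cfg) * cfg.bytes_per_cell
        if total + cost > cfg.memory_budget:
            break
        batch.append((rid, length))
        total += cost

    lanes = LaneAssignment()
    for rid, length in batch:
        cls = classify_read(length, cfg)
        if cls is ReadClass.ULTRA_LONG:
            lanes.overflow.append(rid)
        elif cls is ReadClass.VERY_LONG:
            lanes.slow_lane.append(rid)
        else:
            lanes.fast_lane.append(rid)
    return [rid for rid, _ in batch], lanes


def run_batch(batch, lanes: LaneAssignment, align_fn) -> BatchResult:
    """Align every read of a batch exactly once.

    ``align_fn(read_id)`` must be a pure function of the read; lanes only
    describe *where* work would run, so results are independent of the
    lane assignment and of execution order. A failure on one read is
    recorded under its id and does not abort the rest of the batch.
    """
    order = [rid for rid in lanes.all_ids() if rid in set(batch)]
    missing = [rid for rid in batch if rid not in set(order)]
    results: dict = {}
    failures: dict = {}
    for rid in order + missing:
        try:
            results[rid] = align_fn(rid)
        except Exception as exc:  # noqa: BLE001 - per-read fault isolation
            failures[rid] = exc
    return BatchResult(results=results, failures=failures)
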