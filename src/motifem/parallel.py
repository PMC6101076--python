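"""Work-partitioning plans for the score sweep, with a serial-equivalence
contract.

Three pure partitioning strategies describe how the (k, l) score cells of a
seed sweep are split across logical workers:

``groupwise``
    One worker group per seed sequence (round-robin when there are fewer
    groups than sequences); within a group each target row's l-range is cut
    into m near-equal contiguous blocks.  Workers exchange the cyclic score
    vectors after every seed position, so there is one synchronization point
    per iteration.

``loopswap``
    The outer loop runs over the seed position j instead of the seed
    sequence; for a fixed j all seed sequences are processed before a single
    synchronization.  This trades larger per-worker tasks for roughly n
    times fewer sync points and suits datasets with few long sequences.

``shifted``
    Each worker's blocks shift right by one position per iteration so every
    recurrence input was produced by the same worker in the previous
    iteration; the l=0 boundary cell is recomputed directly by the worker
    owning the lowest block, which also absorbs each new diagonal it starts.
    No intra-sweep synchronization at all — but only valid on single-strand
    (revcomp off) searches.

Plans are data, not threads: ``execute_plan`` runs the blocks in a
deterministic order (optionally spread over weighted worker pools, a pure
scheduling contract) and is bit-identical to the serial sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from motifem.seqio import SequenceDataset
from motifem.scoring import SweepContext
from motifem.startpoints import SequenceMax

STRATEGIES = ("groupwise", "loopswap", "shifted")


@dataclass(frozen=True)
class Block:
    """A contiguous run of cells [lo, hi) in target row ``r`` for a worker."""

    worker: int
    r: int
    lo: int
    hi: int


def _split(size: int, parts: int) -> list[tuple[int, int]]:
    """Near-equal contiguous split of [0, size) into ``parts`` ranges."""
    base, rem = divmod(size, parts)
    out, lo = [], 0
    for p in range(parts):
        hi = lo + base + (1 if p < rem else 0)
        out.append((lo, hi))
        lo = hi
    return out


@dataclass
class PartitionPlan:
    """Pure mapping (worker, seed, iteration) -> disjoint covering blocks."""

    strategy: str
    workers: int
    group_size: int
    row_sizes: list[int]
    seed_ids: list[int]
    seed_positions: dict[int, int]  # seed id -> number of positions M_i
    order: str  # "by_seed" | "by_position"
    n_groups: int = 1
    _base_splits: dict[int, list[tuple[int, int]]] = field(default_factory=dict)

    def _group_of(self, i: int) -> int:
        return self.seed_ids.index(i) % self.n_groups

    def assignment(self, i: int, j: int) -> list[Block]:
        """Blocks covering every (row, l) cell of seed i at iteration j."""
        if i not in self.seed_positions:
            raise ValueError(f"sequence {i} is not a seed in this plan")
        if not 0 <= j < self.seed_positions[i]:
            raise ValueError(f"iteration {j} out of range for seed {i}")
        blocks: list[Block] = []
        if self.strategy in ("groupwise", "loopswap"):
            m = self.group_size if self.strategy == "groupwise" else self.workers
            base = (self._group_of(i) * m) if self.strategy == "groupwise" else 0
            for r, size in enumerate(self.row_sizes):
                for p, (lo, hi) in enumerate(_split(size, m)):
                    if hi > lo:
                        blocks.append(Block(base + p, r, lo, hi))
        elif self.strategy == "shifted":
            for r, size in enumerate(self.row_sizes):
                splits = _split(size, self.workers)
                for w, (lo, hi) in enumerate(splits):
                    if w == 0:
                        lo2, hi2 = 0, min(hi + j, size)
                    else:
                        lo2, hi2 = min(lo + j, size), min(hi + j, size)
                    if hi2 > lo2:
                        blocks.append(Block(w, r, lo2, hi2))
        else:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        return blocks

    def sync_points(self, i: int) -> list[int]:
        """Iteration indices of seed i after which workers must synchronize."""
        if self.strategy == "groupwise":
            return list(range(self.seed_positions[i]))
        if self.strategy == "loopswap":
            # one shared sync per position j, attributed to the longest sweep
            return list(range(self.seed_positions[i]))
        return []

    def total_sync_points(self) -> int:
        """Cross-worker synchronizations over the whole search."""
        if self.strategy == "groupwise":
            return sum(self.seed_positions.values())
        if self.strategy == "loopswap":
            return max(self.seed_positions.values())
        return 0

    def owner(self, i: int, j: int, r: int, l: int) -> int:
        for b in self.assignment(i, j):
            if b.r == r and b.lo <= l < b.hi:
                return b.worker
        raise ValueError(f"cell (row {r}, l={l}) uncovered at iteration {j}")


def _plan_common(dataset: SequenceDataset, W: int):
    from motifem.scoring import target_rows

    rows = [r for r in target_rows(dataset, W) if len(r.codes) >= W]
    row_sizes = [len(r.codes) - W + 1 for r in rows]
    seed_ids = [i for i in range(dataset.n) if len(dataset.sequences[i]) >= W]
    seed_positions = {i: len(dataset.sequences[i]) - W + 1 for i in seed_ids}
    return row_sizes, seed_ids, seed_positions


def plan_groupwise(dataset: SequenceDataset, W: int, workers: int = 1,
                   group_size: int = 1) -> PartitionPlan:
    """Algorithm-2-style plan: worker groups sweep seed sequences."""
    if workers < 1:
        raise ValueError("workers must be >= 1")
    if group_size < 1 or group_size > workers:
        raise ValueError("group_size must be in [1, workers]")
    row_sizes, seed_ids, seed_positions = _plan_common(dataset, W)
    n_groups = max(1, workers // group_size)
    return PartitionPlan("groupwise", workers, group_size, row_sizes,
                         seed_ids, seed_positions, order="by_seed",
                         n_groups=n_groups)


def plan_loopswap(dataset: SequenceDataset, W: int,
                  workers: int = 1) -> PartitionPlan:
    """Algorithm-3-style plan: outer loop over position j, sync once per j."""
    if workers < 1:
        raise ValueError("workers must be >= 1")
    row_sizes, seed_ids, seed_positions = _plan_common(dataset, W)
    return PartitionPlan("loopswap", workers, workers, row_sizes,
                         seed_ids, seed_positions, order="by_position",
                         n_groups=1)


def plan_shifted(dataset: SequenceDataset, W: int,
                 workers: int = 1) -> PartitionPlan:
    """Shifted-block plan with zero intra-sweep synchronization.

    Only available on single-strand searches; the reverse-strand rows of a
    revcomp search break the same-worker dependency guarantee.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    if dataset.revcomp_enabled:
        raise ValueError("shifted strategy is unavailable with revcomp")
    row_sizes, seed_ids, seed_positions = _plan_common(dataset, W)
    return PartitionPlan("shifted", workers, workers, row_sizes,
                         seed_ids, seed_positions, order="by_seed",
                         n_groups=1)


def choose_strategy(n_sequences: int, threshold: int = 16) -> str:
    """Loop-swapped plan for few sequences, group-wise otherwise."""
    if n_sequences < 1:
        raise ValueError("need at least one sequence")
    return "loopswap" if n_sequences < threshold else "groupwise"


def dependency_report(plan: PartitionPlan, i: int) -> dict:
    """Audit the recurrence dependencies of seed i under a plan.

    Every cell with l >= 1 at iteration j >= 1 is computed by the recurrence
    from its diagonal predecessor (j-1, l-1).  The report counts
    predecessors owned by a different worker and how many of those are
    covered by a synchronization point at the end of iteration j-1.
    """
    cross = 0
    uncovered = 0
    syncs = set(plan.sync_points(i))
    for j in range(1, plan.seed_positions[i]):
        owners_prev = {}
        for b in plan.assignment(i, j - 1):
            for l in range(b.lo, b.hi):
                owners_prev[(b.r, l)] = b.worker
        for b in plan.assignment(i, j):
            for l in range(max(b.lo, 1), b.hi):
                w_prev = owners_prev[(b.r, l - 1)]
                if w_prev != b.worker:
                    cross += 1
                    if (j - 1) not in syncs:
                        uncovered += 1
    return {
        "cross_worker_deps": cross,
        "uncovered_cross_worker_deps": uncovered,
        "sync_points": len(syncs),
    }


def coverage_errors(plan: PartitionPlan, i: int) -> int:
    """Number of (iteration, cell) pairs not covered exactly once."""
    errors = 0
    for j in range(plan.seed_positions[i]):
        count = [np.zeros(size, dtype=int) for size in plan.row_sizes]
        for b in plan.assignment(i, j):
            count[b.r][b.lo:b.hi] += 1
        errors += int(sum((c != 1).sum() for c in count))
    return errors


@dataclass
class ExecutionReport:
    strategy: str
    sync_points: int
    pools: tuple[int, ...]
    worker_pool: list[int]
    seeds_swept: int


def _assign_pools(workers: int, pools: tuple[int, ...]) -> list[int]:
    """Map workers to weighted pools (largest-remainder apportionment)."""
    if not pools or any(w <= 0 for w in pools):
        raise ValueError("pool weights must be positive")
    total = sum(pools)
    quota = [workers * w / total for w in pools]
    counts = [int(q) for q in quota]
    for _ in range(workers - sum(counts)):
        rema = [q - c for q, c in zip(quota, counts)]
        counts[int(np.argmax(rema))] += 1
    mapping = []
    for pool_idx, c in enumerate(counts):
        mapping.extend([pool_idx] * c)
    return mapping[:workers]


def execute_plan(plan: PartitionPlan, ctx: SweepContext, consume,
                 pools: tuple[int, ...] = (1,),
                 audit: list | None = None) -> ExecutionReport:
    """Execute a partition plan against a sweep context.

    Blocks run in a fixed deterministic order (iteration, worker, row); the
    per-cell arithmetic is identical to the serial sweep, so results match
    it exactly regardless of worker count or pool weights.  ``consume(i, j,
    local_maxima)`` receives the worker-local per-block maxima once an
    iteration's blocks are complete.  ``audit``, if given, collects
    ``(i, j, r, lo, hi, worker, mode)`` records.

    Workers are a logical contract: execution here is serial, and the
    weighted pools only determine the worker-to-pool mapping recorded in the
    report (mirroring a host/coprocessor workload split).
    """
    if plan.row_sizes != ctx.row_sizes:
        raise ValueError("plan does not match the sweep context")
    worker_pool = _assign_pools(plan.workers, tuple(pools))
    dataset = ctx.dataset
    sync_count = 0
    seeds_swept = 0

    buffers: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def run_iteration(i: int, j: int) -> None:
        nonlocal sync_count
        prev, cur = buffers[i]
        seed_codes = dataset.codes[i]
        blocks = sorted(plan.assignment(i, j),
                        key=lambda b: (b.worker, b.r, b.lo))
        locals_: list[SequenceMax] = []
        for b in blocks:
            s = ctx.starts[b.r]
            if j == 0:
                ctx.direct_cells(seed_codes, j, np.arange(s + b.lo, s + b.hi),
                                 cur)
                if audit is not None:
                    audit.append((i, j, b.r, b.lo, b.hi, b.worker, "direct"))
            else:
                lo = b.lo
                if lo == 0:
                    ctx.direct_cells(seed_codes, j, np.array([s]), cur)
                    if audit is not None:
                        audit.append((i, j, b.r, 0, 1, b.worker, "direct"))
                    lo = 1
                if b.hi > lo:
                    ctx.advance_slice(seed_codes, j, prev, cur,
                                      s + lo, s + b.hi)
                    if audit is not None:
                        audit.append((i, j, b.r, lo, b.hi, b.worker,
                                      "recurrence"))
            vec = cur[s + b.lo:s + b.hi]
            l = int(np.argmax(vec)) + b.lo
            row = ctx.rows[b.r]
            locals_.append(SequenceMax(row.k, l, row.strand,
                                       float(cur[s + l]), local=True))
        consume(i, j, locals_)
        buffers[i] = (cur, prev)
        if j in set(plan.sync_points(i)):
            sync_count += 1

    if plan.order == "by_seed":
        for i in plan.seed_ids:
            buffers[i] = (np.empty(ctx.M), np.empty(ctx.M))
            for j in range(plan.seed_positions[i]):
                run_iteration(i, j)
            seeds_swept += 1
            del buffers[i]
    else:  # by_position (loopswap)
        for i in plan.seed_ids:
            buffers[i] = (np.empty(ctx.M), np.empty(ctx.M))
        max_pos = max(plan.seed_positions.values())
        for j in range(max_pos):
            for i in plan.seed_ids:
                if j < plan.seed_positions[i]:
                    run_iteration(i, j)
        seeds_swept = len(plan.seed_ids)
        sync_count = plan.total_sync_points()

    return ExecutionReport(strategy=plan.strategy, sync_points=sync_count,
                           pools=tuple(pools), worker_pool=worker_pool,
                           seeds_swept=seeds_swept)
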