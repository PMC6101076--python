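"""Starting-point search: per-sequence maxima, ranking, LLR and the heap.

For every seed window (i, j) the search scores all target windows, keeps the
highest-scoring window of each sequence (per strand in revcomp mode), sorts
those per-sequence maxima by decreasing score, and converts the top-nsites
prefixes into candidate motif models ranked by log-likelihood ratio against
the background.  The best candidates per (width, nsites) are retained in a
bounded heap, deduplicated by seed, and later refined by EM.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from motifem.seqio import ALPHABET_SIZE, SequenceDataset, encode
from motifem.scoring import (
    LetterMatrix,
    SweepContext,
    build_letter_matrix,
)

logger = logging.getLogger(__name__)

_LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SequenceMax:
    """Best-scoring width-W window of sequence k (possibly worker-local)."""

    k: int
    maxk: int
    strand: str
    score: float
    local: bool = False


@dataclass
class MotifModel:
    """Letter-frequency motif model theta: 4 x (W+1), column 0 = background."""

    theta: np.ndarray
    W: int

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (ALPHABET_SIZE, self.W + 1):
            raise ValueError("theta must be 4 x (W+1)")
        colsums = self.theta.sum(axis=0)
        if (not np.all(np.isfinite(self.theta)) or np.any(self.theta < 0)
                or np.any(np.abs(colsums - 1.0) > 1e-9)):
            raise ValueError("theta columns must be frequency vectors")

    def consensus(self) -> str:
        from motifem.seqio import ALPHABET
        return "".join(ALPHABET[a] for a in self.theta[:, 1:].argmax(axis=0))


@dataclass
class CandidateStart:
    """A seed substring promoted to a candidate initial motif model."""

    seed: tuple[int, int, int, str]  # (i, j, W, strand)
    nsites: int
    model: MotifModel
    llr: float
    pvalue: float
    sites: list[tuple[int, int, str]] = field(default_factory=list)


class StartHeap:
    """Bounded best-candidate store, one heap per (W, nsites) pair.

    Ordering is by LLR with a deterministic seed tie-break, so the retained
    set is independent of insertion order; a per-group hash set prevents
    duplicate seeds.
    """

    def __init__(self, capacity: int = 5):
        if capacity < 1:
            raise ValueError("heap capacity must be >= 1")
        self.capacity = capacity
        self._heaps: dict[tuple[int, int], list] = {}
        self._seen: dict[tuple[int, int], set] = {}

    @staticmethod
    def _sortkey(llr: float, seed: tuple) -> tuple:
        i, j, _w, strand = seed
        return (llr, -i, -j, strand == "+")

    def would_admit(self, W: int, nsites: int, llr: float,
                    seed: tuple | None = None) -> bool:
        heap = self._heaps.get((W, nsites))
        if heap is None or len(heap) < self.capacity:
            return True
        key = self._sortkey(llr, seed) if seed is not None \
            else (llr, -(2 ** 62), -(2 ** 62), False)
        return key > heap[0][:4]

    def offer(self, cand: CandidateStart) -> bool:
        """Insert a candidate; returns True if it was retained."""
        group = (cand.seed[2], cand.nsites)
        heap = self._heaps.setdefault(group, [])
        seen = self._seen.setdefault(group, set())
        seedkey = cand.seed
        if seedkey in seen:
            return False
        item = self._sortkey(cand.llr, cand.seed) + (cand,)
        if len(heap) < self.capacity:
            heapq.heappush(heap, item)
            seen.add(seedkey)
            return True
        if item[:4] <= heap[0][:4]:
            return False
        evicted = heapq.heapreplace(heap, item)
        seen.discard(evicted[4].seed)
        seen.add(seedkey)
        return True

    def groups(self) -> list[tuple[int, int]]:
        return sorted(self._heaps)

    def candidates(self, W: int | None = None,
                   nsites: int | None = None) -> list[CandidateStart]:
        """Retained candidates, best (highest LLR) first."""
        out = []
        for (w, ns), heap in self._heaps.items():
            if W is not None and w != W:
                continue
            if nsites is not None and ns != nsites:
                continue
            out.extend(heap)
        return [item[4] for item in sorted(out, reverse=True,
                                           key=lambda it: it[:4])]

    def __len__(self) -> int:
        return sum(len(h) for h in self._heaps.values())


# ---------------------------------------------------------------------------
# maxima


def _better(a: SequenceMax, b: SequenceMax) -> bool:
    """Tie-break order: higher score, then lowest position, then + strand."""
    ka = (a.score, -a.maxk, a.strand == "+")
    kb = (b.score, -b.maxk, b.strand == "+")
    return ka > kb


def select_sequence_maxima(scores, rows, n: int) -> list[SequenceMax]:
    """One global :class:`SequenceMax` per sequence from complete score rows.

    ``scores`` is a list of per-row score vectors aligned with ``rows``
    (forward rows, then reverse rows in revcomp mode); the better of the two
    strands is kept per sequence.
    """
    best: dict[int, SequenceMax] = {}
    for vec, row in zip(scores, rows):
        if len(vec) == 0:
            raise ValueError(f"empty score row for sequence {row.k}")
        l = int(np.argmax(vec))  # lowest position wins ties
        cand = SequenceMax(row.k, l, row.strand, float(vec[l]))
        if row.k not in best or _better(cand, best[row.k]):
            best[row.k] = cand
    if len(best) != n:
        raise ValueError("score rows do not cover every sequence")
    return [best[k] for k in sorted(best)]


def merge_local_maxima(locals_: list[SequenceMax]) -> list[SequenceMax]:
    """Merge worker-local per-sequence maxima into global ones.

    The result equals the serial per-sequence maximum and is independent of
    worker count and merge order (the tie-break is a total order).
    """
    best: dict[int, SequenceMax] = {}
    for m in locals_:
        if m.k not in best or _better(m, best[m.k]):
            best[m.k] = m
    out = [
        SequenceMax(m.k, m.maxk, m.strand, m.score, local=False)
        for m in (best[k] for k in sorted(best))
    ]
    return out


# ---------------------------------------------------------------------------
# ranking, models, LLR, P-values


def nsites_grid(n: int) -> list[int]:
    """Geometric nsites grid {max(2, ceil(n/2^t))} doubling up to n."""
    if n < 2:
        raise ValueError("need at least 2 sequences")
    vals = set()
    for t in range(int(math.floor(math.log2(n))), -1, -1):
        vals.add(min(n, max(2, math.ceil(n / 2 ** t))))
    return sorted(vals)


def rank_candidates(maxima: list[SequenceMax], model: str = "oops",
                    grid: list[int] | None = None):
    """Sort maxima by decreasing score and emit (nsites, site-prefix) sets.

    OOPS evaluates nsites = n only; ZOOPS evaluates an nsites grid and takes
    the top-nsites prefix of the sorted maxima for each value.
    """
    n = len(maxima)
    if n < 2:
        raise ValueError("need at least 2 sequences to align")
    order = sorted(maxima, key=lambda m: (-m.score, m.k))
    if model == "oops":
        sizes = [n]
    elif model == "zoops":
        sizes = grid if grid is not None else nsites_grid(n)
        if any(ns < 2 or ns > n for ns in sizes):
            raise ValueError("nsites grid values must lie in [2, n]")
    else:
        raise ValueError(f"unknown occurrence model {model!r}")
    return [(ns, order[:ns]) for ns in sizes]


def _site_codes(site) -> np.ndarray:
    if isinstance(site, str):
        return encode(site)
    return np.asarray(site, dtype=np.uint8)


def sites_to_model(sites, background, pseudocount: float = 0.0,
                   W: int | None = None) -> MotifModel:
    """Letter-frequency model from aligned width-W site windows.

    theta[x][p] = (count_p(x) + pseudocount * bg(x)) / (nsites + pseudocount)
    for motif columns p = 1..W; column 0 is the background itself.
    """
    mats = [_site_codes(s) for s in sites]
    if not mats:
        raise ValueError("need at least one site")
    widths = {len(m) for m in mats}
    if len(widths) != 1:
        raise ValueError("site windows must share one width")
    if W is not None and widths != {W}:
        raise ValueError("site width does not match W")
    W = widths.pop()
    bg = np.asarray(background, dtype=float)
    X = np.stack(mats)
    counts = np.zeros((ALPHABET_SIZE, W))
    np.add.at(counts, (X, np.broadcast_to(np.arange(W), X.shape)), 1.0)
    theta = np.empty((ALPHABET_SIZE, W + 1))
    theta[:, 0] = bg
    theta[:, 1:] = (counts + pseudocount * bg[:, None]) / (len(mats) + pseudocount)
    return MotifModel(theta, W)


def weighted_llr(model: MotifModel, sites, background,
                 column_weights: np.ndarray | None = None) -> float:
    """Log-likelihood ratio (bits) of the site set under the model vs background.

    Sum over sites and motif columns of ``log2(theta[x][p] / bg(x))``.  An
    optional per-column weight vector (e.g. information content) can scale
    the column contributions; unweighted by default.
    """
    bg = np.asarray(background, dtype=float)
    with np.errstate(divide="ignore"):
        # -inf entries correspond to letters never observed at a column and
        # are only reachable when a site contradicts its own model
        lg = np.log2(model.theta[:, 1:] / bg[:, None])
    if column_weights is not None:
        lg = lg * np.asarray(column_weights, dtype=float)[None, :]
    total = 0.0
    cols = np.arange(model.W)
    for s in sites:
        total += float(lg[_site_codes(s), cols].sum())
    return total


def candidate_pvalue(llr: float, nsites: int, W: int,
                     background=None) -> float:
    """Tail probability of reaching ``llr`` under the background null.

    Chi-square upper-tail approximation with (|alphabet|-1)*W degrees of
    freedom applied to the deviance ``2*ln(2)*llr``; monotone decreasing in
    llr and saturating at 1.
    """
    if not np.isfinite(llr):
        raise ValueError("llr must be finite")
    if llr <= 0:
        return 1.0
    df = (ALPHABET_SIZE - 1) * W
    p = float(chi2.sf(2.0 * _LN2 * llr, df))
    return max(p, 5e-324)


# ---------------------------------------------------------------------------
# the search


@dataclass
class SearchConfig:
    """Knobs of the starting-point search (occurrence model + execution)."""

    model: str = "oops"
    heap_capacity: int = 5
    match_weight: float = 0.6
    mat: LetterMatrix | None = None
    strategy: str = "serial"  # serial|auto|groupwise|loopswap|shifted
    workers: int = 1
    group_size: int = 1
    strategy_threshold: int = 16
    pool_weights: tuple[int, ...] = (1,)
    pseudocount_rate: float = 0.01  # pseudocount = rate * nsites
    nsites: list[int] | None = None  # explicit ZOOPS grid override


@dataclass
class SearchResult:
    heap: StartHeap
    W: int
    strategy: str
    counters: dict

    def top(self) -> CandidateStart | None:
        cands = self.heap.candidates(W=self.W)
        return cands[0] if cands else None


def resolve_strategy(config: SearchConfig, dataset: SequenceDataset) -> str:
    from motifem.parallel import choose_strategy

    s = config.strategy
    if s == "auto":
        if not dataset.revcomp_enabled:
            return "shifted"
        return choose_strategy(dataset.n, config.strategy_threshold)
    if s == "shifted" and dataset.revcomp_enabled:
        raise ValueError("shifted strategy is unavailable with revcomp")
    return s


class _SeedEvaluator:
    """Turns per-seed maxima into ranked candidates and heap updates."""

    def __init__(self, dataset: SequenceDataset, W: int, config: SearchConfig,
                 heap: StartHeap, n_targets: int | None = None):
        self.dataset = dataset
        self.W = W
        self.config = config
        self.heap = heap
        self.bg = np.asarray(dataset.background, dtype=float)
        self._log_bg_col = np.log2(self.bg)[:, None]
        n_eff = n_targets if n_targets is not None else dataset.n
        if config.model == "zoops":
            self.grid = config.nsites if config.nsites is not None \
                else nsites_grid(n_eff)
        else:
            self.grid = [n_eff]

    def window(self, m: SequenceMax) -> np.ndarray:
        src = self.dataset.codes if m.strand == "+" else self.dataset.rc_codes
        return src[m.k][m.maxk:m.maxk + self.W]

    def evaluate(self, i: int, j: int, maxima: list[SequenceMax]) -> None:
        W, bg = self.W, self.bg
        order = sorted(maxima, key=lambda m: (-m.score, m.k))
        X = np.stack([self.window(m) for m in order])
        onehot = np.zeros((len(order), ALPHABET_SIZE, W))
        onehot[np.arange(len(order))[:, None], X, np.arange(W)[None, :]] = 1.0
        csum = onehot.cumsum(axis=0)
        seed = (i, j, W, "+")
        for ns in self.grid:
            counts = csum[ns - 1]
            pc = self.config.pseudocount_rate * ns
            theta_motif = (counts + pc * bg[:, None]) / (ns + pc)
            llr = float(
                (counts * (np.log2(theta_motif) - self._log_bg_col)).sum()
            )
            if not self.heap.would_admit(W, ns, llr, seed):
                continue
            theta = np.empty((ALPHABET_SIZE, W + 1))
            theta[:, 0] = bg
            theta[:, 1:] = theta_motif
            cand = CandidateStart(
                seed=seed,
                nsites=ns,
                model=MotifModel(theta, W),
                llr=llr,
                pvalue=candidate_pvalue(llr, ns, W),
                sites=[(m.k, m.maxk, m.strand) for m in order[:ns]],
            )
            self.heap.offer(cand)


def _maxima_from_flat(flat_row: np.ndarray, ctx: SweepContext,
                      n_targets: int) -> list[SequenceMax]:
    best: dict[int, SequenceMax] = {}
    for r, row in enumerate(ctx.rows):
        s, e = ctx.starts[r], ctx.starts[r + 1]
        vec = flat_row[s:e]
        l = int(np.argmax(vec))
        cand = SequenceMax(row.k, l, row.strand, float(vec[l]))
        if row.k not in best or _better(cand, best[row.k]):
            best[row.k] = cand
    if len(best) != n_targets:
        raise ValueError("score sweep does not cover every target sequence")
    return [best[k] for k in sorted(best)]


def search_starting_points(dataset: SequenceDataset, W: int,
                           config: SearchConfig | None = None) -> SearchResult:
    """Run the full starting-point search for one motif width.

    Iterates every seed window (i, j), computes the pair scores of all
    target windows via the incremental recurrence, selects per-sequence
    maxima, ranks candidate site sets, and keeps the top candidates per
    (W, nsites) in a bounded heap.  The result is deterministic and
    identical under every execution strategy and worker count.
    """
    from motifem import parallel

    if config is None:
        config = SearchConfig()
    if dataset.n < 2:
        raise ValueError("need at least 2 sequences")
    if W < 1:
        raise ValueError("width must be >= 1")
    if W > max(dataset.lengths):
        raise ValueError(f"width {W} exceeds every sequence length")
    strategy = resolve_strategy(config, dataset)
    mat = config.mat if config.mat is not None else build_letter_matrix(
        dataset.background, config.match_weight)
    ctx = SweepContext(dataset, W, mat)
    heap = StartHeap(config.heap_capacity)
    n_targets = len({row.k for row in ctx.rows})
    if n_targets < 2:
        raise ValueError("need at least 2 sequences of length >= W")
    evaluator = _SeedEvaluator(dataset, W, config, heap, n_targets=n_targets)

    seed_ids = []
    for i in range(dataset.n):
        if len(dataset.sequences[i]) < W:
            logger.warning("sequence %s shorter than width %d: skipped as seed",
                           dataset.ids[i], W)
        else:
            seed_ids.append(i)
    if not seed_ids:
        raise ValueError("no sequence long enough to seed the search")

    sync_points = 0
    seeds_evaluated = 0
    if strategy == "serial":
        for i in seed_ids:
            for j, flat_row in ctx.sweep(i):
                maxima = _maxima_from_flat(flat_row, ctx, n_targets)
                evaluator.evaluate(i, j, maxima)
                seeds_evaluated += 1
    else:
        if strategy == "groupwise":
            plan = parallel.plan_groupwise(dataset, W, config.workers,
                                           config.group_size)
        elif strategy == "loopswap":
            plan = parallel.plan_loopswap(dataset, W, config.workers)
        elif strategy == "shifted":
            plan = parallel.plan_shifted(dataset, W, config.workers)
        else:
            raise ValueError(f"unknown strategy {strategy!r}")

        def consume(i, j, local_maxima):
            nonlocal seeds_evaluated
            maxima = merge_local_maxima(local_maxima)
            if len(maxima) != n_targets:
                raise ValueError("incomplete local maxima")
            evaluator.evaluate(i, j, maxima)
            seeds_evaluated += 1

        report = parallel.execute_plan(plan, ctx, consume,
                                       pools=config.pool_weights)
        sync_points = report.sync_points

    counters = {
        "cells_direct": ctx.n_direct,
        "cells_recurrence": ctx.n_recurrence,
        "cells_total": ctx.cells_computed,
        "sync_points": sync_points,
        "seeds_evaluated": seeds_evaluated,
        "workers": config.workers,
        "pool_weights": tuple(config.pool_weights),
    }
    return SearchResult(heap=heap, W=W, strategy=strategy, counters=counters)


def width_schedule(minw: int = 8, maxw: int = 50, count: int = 7) -> list[int]:
    """Geometric width grid: ``count`` widths from minw, spaced by ~sqrt(2)."""
    if minw < 1 or maxw < minw:
        raise ValueError("need 1 <= minw <= maxw")
    ws = sorted({min(maxw, round(minw * 2 ** (t / 2))) for t in range(count)})
    return ws
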