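"""Pairwise substring probability scores and their incremental recurrence.

The score of a pair of width-W windows, ``P(S_i,j, S_k,l)``, is the sum over
the W aligned positions of a 4x4 letter matrix ``mat``::

    P(S_i,j, S_k,l) = sum_{p=0..W-1} mat[S_i(j+p)][S_k(l+p)]

Sliding the seed window one position to the right maps each cell onto a
diagonal predecessor, giving an O(1)-per-cell recurrence::

    P(S_i,j, S_k,l) = P(S_i,j-1, S_k,l-1)
                      + mat[S_i(j+W-1)][S_k(l+W-1)]
                      - mat[S_i(j-1)][S_k(l-1)]

with the ``l = 0`` column (and the whole ``j = 0`` row) computed directly.
Two row buffers are swapped between iterations rather than reallocated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from motifem.seqio import ALPHABET_SIZE, SequenceDataset, encode


@dataclass
class LetterMatrix:
    """The 4x4 letter matrix entering the pair score."""

    values: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (ALPHABET_SIZE, ALPHABET_SIZE):
            raise ValueError("letter matrix must be 4x4")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("letter matrix entries must be finite")


def build_letter_matrix(
    background: np.ndarray | None = None,
    match_weight: float = 0.6,
    mode: str = "logratio",
) -> LetterMatrix:
    """Construct the letter matrix ``mat``.

    The default single-parameter match model scores a pair of letters by the
    log-odds of the pair arising from a common site versus background::

        mat[a][b] = log2( (w*delta(a,b) + (1-w)*bg(a)) / bg(a) )

    so identical letters score positively and mismatches score
    ``log2(1 - w) < 0``.  ``mode="indicator"`` returns the 0/1 identity
    matrix (useful as a match-count oracle).
    """
    if mode == "indicator":
        return LetterMatrix(np.eye(ALPHABET_SIZE), "indicator")
    if mode != "logratio":
        raise ValueError(f"unknown letter-matrix mode {mode!r}")
    if background is None:
        background = np.full(ALPHABET_SIZE, 0.25)
    bg = np.asarray(background, dtype=float)
    if np.any(bg <= 0):
        raise ValueError("background entries must be positive (apply a floor)")
    if not 0 < match_weight <= 1:
        raise ValueError("match_weight must be in (0, 1]")
    num = match_weight * np.eye(ALPHABET_SIZE) + (1 - match_weight) * bg[:, None]
    vals = np.log2(num / bg[:, None])
    return LetterMatrix(vals, f"logratio(match_weight={match_weight})")


def serialize_letter_matrix(mat: LetterMatrix) -> str:
    """4x4 whitespace table with A C G T header row/column."""
    lines = ["  " + "  ".join("ACGT")]
    for a, row in zip("ACGT", mat.values):
        lines.append(a + " " + " ".join(f"{v:.6g}" for v in row))
    return "\n".join(lines) + "\n"


def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, str):
        return encode(seq)
    return np.asarray(seq, dtype=np.uint8)


def score_pair_direct(si, j: int, sk, l: int, W: int, mat: LetterMatrix) -> float:
    """Direct evaluation of P(S_i,j, S_k,l): sum of W letter-matrix entries."""
    ci, ck = _as_codes(si), _as_codes(sk)
    if j < 0 or j + W > len(ci) or l < 0 or l + W > len(ck):
        raise ValueError("window overruns sequence bounds")
    return float(mat.values[ci[j:j + W], ck[l:l + W]].sum())


class TargetRow(NamedTuple):
    """One row of score cells: all window starts of sequence k on a strand."""

    k: int
    strand: str  # '+' or '-'
    codes: np.ndarray


def target_rows(dataset: SequenceDataset, W: int) -> list[TargetRow]:
    """Forward rows for every sequence, plus reverse rows in revcomp mode."""
    rows = [TargetRow(k, "+", dataset.codes[k]) for k in range(dataset.n)]
    if dataset.revcomp_enabled:
        rows += [TargetRow(k, "-", dataset.rc_codes[k])
                 for k in range(dataset.n)]
    return rows


class SweepContext:
    """Precomputed layout and kernels for one (dataset, W, mat) sweep.

    Score cells for a fixed seed window are stored as one flat vector
    covering every target row; ``starts[r]`` is the offset of row r and the
    cell for (row r, offset l) sits at ``starts[r] + l``.  The context owns
    the instrumentation counters (cells computed directly vs by recurrence)
    used for the complexity property.
    """

    def __init__(self, dataset: SequenceDataset, W: int, mat: LetterMatrix):
        if W < 1:
            raise ValueError("width must be >= 1")
        self.dataset = dataset
        self.W = W
        self.mat = mat
        self.rows = [r for r in target_rows(dataset, W)
                     if len(r.codes) >= W]
        sizes = [len(r.codes) - W + 1 for r in self.rows]
        self.row_sizes = sizes
        self.starts = np.concatenate(([0], np.cumsum(sizes)))
        self.M = int(self.starts[-1])
        # per flat cell: window codes (M x W) for direct evaluation
        self.win_codes = np.concatenate([
            np.lib.stride_tricks.sliding_window_view(r.codes, W)
            for r in self.rows
        ]).astype(np.uint8)
        # recurrence gather indices; entries at row starts are never used
        add = np.zeros(self.M, dtype=np.uint8)
        sub = np.zeros(self.M, dtype=np.uint8)
        for r, row in enumerate(self.rows):
            s, e = self.starts[r], self.starts[r + 1]
            add[s + 1:e] = row.codes[W:e - s - 1 + W]
            sub[s + 1:e] = row.codes[:e - s - 1]
        self.add_codes = add
        self.sub_codes = sub
        self.n_direct = 0
        self.n_recurrence = 0

    # -- kernels ---------------------------------------------------------

    def direct_cells(self, seed_codes: np.ndarray, j: int,
                     idx, out: np.ndarray) -> None:
        """Direct evaluation of the flat cells ``idx`` into ``out[idx]``."""
        idx = np.atleast_1d(np.asarray(idx))
        seed_win = seed_codes[j:j + self.W][None, :]
        out[idx] = self.mat.values[seed_win, self.win_codes[idx]].sum(axis=1)
        self.n_direct += idx.size

    def direct_full_row(self, seed_codes: np.ndarray, j: int,
                        out: np.ndarray) -> None:
        seed_win = seed_codes[j:j + self.W][None, :]
        out[:] = self.mat.values[seed_win, self.win_codes].sum(axis=1)
        self.n_direct += self.M

    def advance_slice(self, seed_codes: np.ndarray, j: int,
                      prev: np.ndarray, out: np.ndarray,
                      lo: int, hi: int) -> None:
        """Recurrence update of flat cells [lo, hi); cells must have l >= 1."""
        add_row = self.mat.values[seed_codes[j + self.W - 1]]
        sub_row = self.mat.values[seed_codes[j - 1]]
        out[lo:hi] = (prev[lo - 1:hi - 1]
                      + add_row[self.add_codes[lo:hi]]
                      - sub_row[self.sub_codes[lo:hi]])
        self.n_recurrence += hi - lo

    def advance_full(self, seed_codes: np.ndarray, j: int,
                     prev: np.ndarray, out: np.ndarray) -> None:
        """One full-row recurrence step; row-start (l=0) cells done directly."""
        if self.M > 1:
            self.advance_slice(seed_codes, j, prev, out, 1, self.M)
            # row starts (l=0) picked up garbage from the previous row's tail
            self.n_recurrence -= len(self.rows) - 1
        self.direct_cells(seed_codes, j, self.starts[:-1], out)

    def sweep(self, i: int):
        """Serial sweep over seed positions j for seed sequence i.

        Yields ``(j, flat_row)``; the two row buffers are swapped, never
        reallocated.  The yielded array is reused — consume it before the
        next iteration.
        """
        seed_codes = self.dataset.codes[i]
        n_pos = len(seed_codes) - self.W + 1
        if n_pos < 1:
            raise ValueError("seed sequence shorter than width")
        prev = np.empty(self.M)
        cur = np.empty(self.M)
        for j in range(n_pos):
            if j == 0:
                self.direct_full_row(seed_codes, 0, cur)
            else:
                self.advance_full(seed_codes, j, prev, cur)
            yield j, cur
            prev, cur = cur, prev

    @property
    def cells_computed(self) -> int:
        return self.n_direct + self.n_recurrence


@dataclass
class ScoreRows:
    """Cyclic pair of per-row score vectors for seed positions j-1 and j."""

    current: list[np.ndarray]
    previous: list[np.ndarray]
    j: int
    n_direct: int = 0
    n_recurrence: int = 0


def score_row_incremental(
    state: ScoreRows | None,
    dataset: SequenceDataset,
    i: int,
    mat: LetterMatrix,
    W: int,
) -> ScoreRows:
    """Advance the score rows of seed sequence i by one position.

    With ``state=None`` the rows are initialized at ``j = 0`` by direct
    evaluation.  Otherwise the two buffers are swapped in place and every
    cell with ``l >= 1`` is updated by the diagonal recurrence while the
    ``l = 0`` cell of each row is recomputed directly.
    """
    rows = [r for r in target_rows(dataset, W) if len(r.codes) >= W]
    seed = dataset.codes[i]
    n_pos = len(seed) - W + 1
    if n_pos < 1:
        raise ValueError("seed sequence shorter than width")
    if state is None:
        cur, prev = [], []
        n_direct = 0
        for r in rows:
            vals = np.array([
                mat.values[seed[0:W], r.codes[l:l + W]].sum()
                for l in range(len(r.codes) - W + 1)
            ])
            cur.append(vals)
            prev.append(np.zeros_like(vals))
            n_direct += len(vals)
        return ScoreRows(cur, prev, 0, n_direct=n_direct)
    j = state.j + 1
    if j >= n_pos:
        raise ValueError(f"seed position {j} out of range for sequence {i}")
    state.current, state.previous = state.previous, state.current
    add_row = mat.values[seed[j + W - 1]]
    sub_row = mat.values[seed[j - 1]]
    for r, row in enumerate(rows):
        prev = state.previous[r]
        cur = state.current[r]
        mk = len(cur)
        if mk > 1:
            cur[1:] = (prev[:-1]
                       + add_row[row.codes[W:mk - 1 + W]]
                       - sub_row[row.codes[:mk - 1]])
            state.n_recurrence += mk - 1
        cur[0] = mat.values[seed[j:j + W], row.codes[0:W]].sum()
        state.n_direct += 1
    state.j = j
    return state
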