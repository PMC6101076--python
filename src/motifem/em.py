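"""EM refinement of starting points under the OOPS and ZOOPS models.

Each candidate initial model theta(0) is refined by
expectation-maximization.  The E step computes, per sequence, a posterior
over site start positions (plus a no-site alternative under ZOOPS, prior
``1 - lambda`` against ``lambda / m_i`` per position, where ``m_i`` is the
number of admissible starts); in revcomp mode the position set is doubled
with reverse-strand windows.  The M step re-estimates the motif columns
from the expected site letter counts (with a Dirichlet pseudocount), the
background column from the expected non-site letters, and ``lambda`` from
the mean site mass.  Iteration stops after a fixed number of rounds or when
the objective moves less than ``tol``.

The tracked objective is the observed-data log likelihood plus the
pseudocount (Dirichlet) log-prior; for this penalized objective EM ascent
is exact, so the trajectory is non-decreasing up to rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from motifem.seqio import ALPHABET_SIZE, SequenceDataset
from motifem.startpoints import CandidateStart, MotifModel

_TINY = 1e-300


@dataclass
class EMState:
    """Mutable EM state: model, site prior, posteriors and objective."""

    model: MotifModel
    lam: float | None  # ZOOPS site-occurrence probability; None under OOPS
    z: list[np.ndarray]  # per-sequence posterior over site positions
    z_nosite: np.ndarray | None  # ZOOPS no-site mass per sequence
    loglik: float
    iter: int = 0
    pseudocount: float = 0.0

    @property
    def model_type(self) -> str:
        return "oops" if self.lam is None else "zoops"


def _window_codes(dataset: SequenceDataset, W: int) -> list[np.ndarray]:
    """Per sequence: (m_i x W) window code matrix; revcomp doubles the rows."""
    wins = []
    for i in range(dataset.n):
        c = dataset.codes[i]
        if len(c) < W:
            raise ValueError(f"sequence {i} shorter than width {W}")
        fwd = np.lib.stride_tricks.sliding_window_view(c, W)
        if dataset.revcomp_enabled:
            rev = np.lib.stride_tricks.sliding_window_view(
                dataset.rc_codes[i], W)
            wins.append(np.concatenate([fwd, rev]))
        else:
            wins.append(fwd)
    return wins


def _log_theta(model: MotifModel) -> tuple[np.ndarray, np.ndarray]:
    with np.errstate(divide="ignore"):
        lt = np.log(np.maximum(model.theta, _TINY))
    return lt[:, 1:], lt[:, 0]


def _penalty(model: MotifModel, background: np.ndarray,
             pseudocount: float) -> float:
    """Dirichlet pseudocount log-prior over all theta columns."""
    if pseudocount == 0:
        return 0.0
    lt = np.log(np.maximum(model.theta, _TINY))
    return float(pseudocount * (background[:, None] * lt).sum())


def e_step(state: EMState, dataset: SequenceDataset) -> EMState:
    """Posterior site-position distribution per sequence, plus the objective.

    OOPS places a site in every sequence (uniform position prior); ZOOPS
    adds a no-site alternative with prior ``1 - lambda``.  Posteriors are
    normalized per sequence; the updated penalized log likelihood is stored
    on the state.
    """
    W = state.model.W
    lt_motif, lt_bg = _log_theta(state.model)
    wins = _window_codes(dataset, W)
    cols = np.arange(W)
    z, z_nosite, loglik = [], [], 0.0
    for i, win in enumerate(wins):
        m = win.shape[0]
        # log ratio of site vs background emission for each window
        s = (lt_motif[win, cols] - lt_bg[win]).sum(axis=1)
        base = float(lt_bg[dataset.codes[i]].sum())
        if state.lam is None:  # OOPS
            norm = logsumexp(s)
            z.append(np.exp(s - norm))
            loglik += base + norm - np.log(m)
        else:
            lam = float(state.lam)
            with np.errstate(divide="ignore"):
                terms = np.concatenate(
                    [s + np.log(max(lam, 0.0)) - np.log(m),
                     [np.log(max(1.0 - lam, 0.0))]]
                )
            norm = logsumexp(terms)
            post = np.exp(terms - norm)
            z.append(post[:-1])
            z_nosite.append(post[-1])
            loglik += base + norm
    new = EMState(
        model=state.model,
        lam=state.lam,
        z=z,
        z_nosite=np.array(z_nosite) if state.lam is not None else None,
        loglik=loglik + _penalty(state.model, dataset.background,
                                 state.pseudocount),
        iter=state.iter,
        pseudocount=state.pseudocount,
    )
    return new


def m_step(state: EMState, dataset: SequenceDataset,
           pseudocount: float | None = None) -> EMState:
    """Re-estimate theta (motif + background columns) and lambda.

    Motif column p accumulates the posterior-weighted letter counts of
    window position p plus ``pseudocount * bg``; the background column is
    re-estimated from the expected non-site letters; lambda becomes the
    mean per-sequence site mass.
    """
    if pseudocount is None:
        pseudocount = state.pseudocount
    W = state.model.W
    bg = np.asarray(dataset.background, dtype=float)
    wins = _window_codes(dataset, W)
    counts = np.zeros((ALPHABET_SIZE, W))
    nonsite = np.zeros(ALPHABET_SIZE)
    site_mass_total = 0.0
    for i, win in enumerate(wins):
        zi = state.z[i]
        ci = np.stack(
            [np.bincount(win[:, p], weights=zi, minlength=ALPHABET_SIZE)
             for p in range(W)], axis=1)
        counts += ci
        total_i = np.bincount(dataset.codes[i], minlength=ALPHABET_SIZE).astype(float)
        nonsite += total_i - ci.sum(axis=1)
        site_mass_total += float(zi.sum())
    if dataset.revcomp_enabled:
        # strand-symmetric background column (A=T, C=G), consistent with the
        # symmetrized background estimate; keeps the EM ascent exact when
        # reverse-strand windows are mixed in
        nonsite = (nonsite + nonsite[::-1]) / 2.0
    nonsite = np.maximum(nonsite, 0.0)
    theta = np.empty((ALPHABET_SIZE, W + 1))
    motif = counts + pseudocount * bg[:, None]
    colmass = motif.sum(axis=0, keepdims=True)
    # zero expected site mass (e.g. lambda driven to 0): fall back to bg
    theta[:, 1:] = np.where(colmass > 0, motif / np.where(colmass > 0,
                                                          colmass, 1.0),
                            bg[:, None])
    bg_col = nonsite + pseudocount * bg
    theta[:, 0] = bg_col / bg_col.sum()
    lam = None
    if state.lam is not None:
        lam = float(site_mass_total / dataset.n)
        lam = min(max(lam, 0.0), 1.0)
    return EMState(
        model=MotifModel(theta, W),
        lam=lam,
        z=state.z,
        z_nosite=state.z_nosite,
        loglik=state.loglik,
        iter=state.iter + 1,
        pseudocount=pseudocount,
    )


@dataclass
class EMResult:
    model: MotifModel
    loglik: float
    sites: list[tuple[int, int, str] | None]  # per sequence (i, pos, strand)
    lam: float | None
    n_iter: int
    trajectory: list[float] = field(default_factory=list)
    start: CandidateStart | None = None


def _map_sites(state: EMState, dataset: SequenceDataset, W: int):
    """MAP site per sequence; ZOOPS reports a site only when site mass wins."""
    sites = []
    for i in range(dataset.n):
        zi = state.z[i]
        if state.lam is not None and state.z_nosite is not None:
            if state.z_nosite[i] >= zi.sum():
                sites.append(None)
                continue
        pos = int(np.argmax(zi))
        m_fwd = dataset.n_positions(i, W)
        if dataset.revcomp_enabled and pos >= m_fwd:
            sites.append((i, pos - m_fwd, "-"))
        else:
            sites.append((i, pos, "+"))
    return sites


def run_em(
    start: CandidateStart,
    dataset: SequenceDataset,
    max_iter: int = 50,
    tol: float = 1e-5,
    model_type: str = "oops",
    pseudocount: float | None = None,
) -> EMResult:
    """EM refinement of one starting point; returns the converged model.

    Runs alternating E/M passes until the penalized log likelihood moves by
    less than ``tol`` or ``max_iter`` rounds elapse.  The default
    pseudocount is ``0.01 * nsites`` of the starting candidate.  ZOOPS
    initializes lambda at nsites/n (clamped away from the lam=1 absorbing
    boundary).
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if model_type not in ("oops", "zoops"):
        raise ValueError(f"unknown occurrence model {model_type!r}")
    if pseudocount is None:
        pseudocount = 0.01 * start.nsites
    lam = None
    if model_type == "zoops":
        lam = min(max(start.nsites / dataset.n, 1e-3), 1.0 - 1e-3)
    state = EMState(model=start.model, lam=lam, z=[], z_nosite=None,
                    loglik=-np.inf, iter=0, pseudocount=pseudocount)
    trajectory: list[float] = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        state = e_step(state, dataset)
        trajectory.append(state.loglik)
        if np.isfinite(prev_ll) and abs(state.loglik - prev_ll) < tol:
            break
        prev_ll = state.loglik
        state = m_step(state, dataset)
    # final posteriors consistent with the returned model
    state = e_step(state, dataset)
    sites = _map_sites(state, dataset, start.model.W)
    return EMResult(model=state.model, loglik=state.loglik, sites=sites,
                    lam=state.lam, n_iter=state.iter, trajectory=trajectory,
                    start=start)


def best_of_starts(
    starts: list[CandidateStart],
    dataset: SequenceDataset,
    max_iter: int = 50,
    tol: float = 1e-5,
    model_type: str = "oops",
) -> EMResult:
    """Refine every starting point and keep the best final log likelihood."""
    if not starts:
        raise ValueError("no starting points supplied")
    results = [run_em(s, dataset, max_iter=max_iter, tol=tol,
                      model_type=model_type) for s in starts]
    return max(results, key=lambda r: r.loglik)


def format_meme(results: list[EMResult], background: np.ndarray,
                revcomp: bool, dataset_n: int) -> str:
    """Minimal MEME-format text block for the discovered motifs."""
    from motifem.seqio import ALPHABET

    lines = ["MEME version 4", "", "ALPHABET= ACGT", ""]
    lines.append("strands: + -" if revcomp else "strands: +")
    lines.append("")
    lines.append("Background letter frequencies")
    lines.append(" ".join(f"{a} {f:.3f}" for a, f in zip(ALPHABET, background)))
    lines.append("")
    for idx, res in enumerate(results, 1):
        W = res.model.W
        nsites = sum(1 for s in res.sites if s is not None)
        llr = res.start.llr if res.start is not None else 0.0
        lines.append(f"MOTIF {res.model.consensus()} MOTIF_{idx}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {W} "
            f"nsites= {nsites} llr= {llr:.2f} E= 0"
        )
        for p in range(1, W + 1):
            lines.append(" " + " ".join(f"{res.model.theta[a, p]:.6f}"
                                        for a in range(ALPHABET_SIZE)))
        lines.append("")
    return "\n".join(lines)
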