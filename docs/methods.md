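# Methods

## Model and search procedure

`motifem` discovers a single ungapped DNA motif per run.  The motif model θ
is a 4×(W+1) column-stochastic matrix: column 0 is the background
(non-motif) letter distribution, columns 1..W the per-position letter
distributions.  Two occurrence models are supported: OOPS (exactly one site
per sequence) and ZOOPS (zero or one site per sequence, with site
probability λ).  The search runs in two stages.

### Starting-point search

Every width-W substring of the input is tried as a seed.  For a seed
window, all target windows (both strands in revcomp mode) are scored with
the additive pair score `P(S_i,j, S_k,l) = Σ_p mat[S_i(j+p)][S_k(l+p)]`,
evaluated by the diagonal recurrence (one add, one subtract per cell) with
the `l = 0` column and the `j = 0` row computed directly.  Scores are
accumulated in double precision; an exhaustive oracle test holds the
recurrence within 1e-9 of direct evaluation (measured drift is ~1e-14 at
these problem sizes, so the optional periodic re-anchoring hook was left
out).  Per seed, the best window of each sequence is kept (ties: lowest
position, then forward strand — the same total order is used when merging
worker-local maxima, which makes the merge result independent of worker
count and merge order), the maxima are sorted by decreasing score, and each
trial site count converts its top-nsites prefix into a candidate model.

* **nsites grid.**  OOPS always uses nsites = n.  ZOOPS uses the geometric
  grid {max(2, ⌈n/2^t⌉)} for t = ⌊log2 n⌋..0 (e.g. {2,3,5,10} at n = 10),
  i.e. candidate site counts that double up to n.  An explicit grid can be
  supplied.
* **Letter matrix.**  The pair score needs a 4×4 letter matrix; we use a
  one-parameter log-odds match model,
  `mat[a][b] = log2((w·δ(a,b) + (1−w)·bg(a))/bg(a))` with match weight
  w = 0.6 by default.  Identical letters score positively, mismatches score
  the constant log2(1−w).  The matrix is user-injectable and an indicator
  (0/1) mode exists for testing; results are not sensitive to w in the
  planted-recovery regimes we exercise, and w is deliberately not exposed
  as a CLI flag.
* **Candidate ranking.**  Candidates are ranked by the per-site
  log-likelihood ratio Σ_sites Σ_p log2(θ[x][p]/bg(x)) computed with the
  pseudocounted model (pseudocount 0.01·nsites).  The ratio is unweighted;
  an optional per-column weight vector exists but is off by default.  The
  reported P-value is the χ² upper tail of the deviance 2·ln2·LLR with
  (|Σ|−1)·W = 3W degrees of freedom — a smooth, monotone significance
  transform of the LLR; heap ordering uses the LLR itself and the P-value
  is reporting-only.
* **Heap.**  The top 5 candidates per (W, nsites) survive, deduplicated by
  seed; ordering uses (llr, seed) as a strict total order, so heap contents
  are independent of insertion order — a prerequisite for cross-strategy
  equivalence.

### EM refinement

Every surviving candidate seeds EM.  The E step computes per-sequence
posteriors over site starts from the likelihood ratio of motif vs
background emission of each window (ZOOPS adds a no-site alternative with
prior 1−λ against λ/m per position; revcomp doubles the position set with
reverse-strand windows).  The M step re-estimates motif columns from the
posterior-weighted letter counts plus a Dirichlet pseudocount
(0.01·nsites of the start, spread by the background), the background
column from the expected non-site letters, and λ from the mean site mass.
In revcomp mode the background column is strand-symmetrized (A=T, C=G),
consistent with the symmetrized background estimate; this keeps the EM
ascent exact when reverse-strand windows are mixed in.

The tracked objective is the observed-data log likelihood plus the
pseudocount log-prior.  For that penalized objective every E/M pass is an
exact ascent step, so the trajectory is non-decreasing (the test tolerance
of −1e-6 absorbs rounding only); the raw unpenalized likelihood would not
carry this guarantee.  Iteration stops when the objective moves < 1e-5 or
after 50 rounds (defaults).  ZOOPS initializes λ at nsites/n clamped to
[1e-3, 1−1e-3] to avoid the absorbing λ = 1 boundary; subsequent updates
are unconstrained, and λ = 0 is a legitimate fixed point.  The best final
objective across starts wins; MAP sites are the posterior argmax per
sequence (ZOOPS reports a site only when site mass exceeds no-site mass).

### Partition plans

The score sweep dominates the cost (Θ(M²) cells for M = Σ(L_i−W+1)), so it
is the unit of partitioning.  Plans are pure data — a mapping from (seed,
iteration) to disjoint covering blocks plus a sync-point schedule — and
`execute_plan` runs them serially in a fixed (iteration, worker, row)
order.  Workers are a logical contract: correctness is established by the
coverage, dependency-audit and serial-equivalence tests, not by true
concurrency.  Weighted worker pools (default 1:3, emulating a
host/coprocessor split) affect only the recorded worker-to-pool mapping,
never results.

* **groupwise** — one m-worker group per seed sequence, round-robin when
  groups < n; each target row's l-range is cut into m near-equal contiguous
  blocks; the two score vectors are swapped after every iteration, costing
  one sync per (seed, iteration).
* **loopswap** — the outer loop runs over position j; for fixed j all seeds
  are processed before one sync, giving max_i(L_i−W+1) total syncs instead
  of Σ_i(L_i−W+1).  The advertised ≈n-fold sync reduction is exact for
  equal-length sequences; for ragged sets the reduction factor is
  Σ(M_i)/max(M_i), which is still ≥ 1 but can be far less than n when one
  sequence dominates — the equal-length case is what the sync-count tests
  assert.
* **shifted** — blocks slide right by one position per iteration so each
  recurrence input was computed by the same worker one iteration earlier.
  A pure +1 shift would leave cells 1..j−1 orphaned, so ownership follows
  the recurrence diagonals: the lowest-block worker recomputes l = 0
  directly each iteration and keeps every diagonal it starts (its block is
  [0, e₀+j)), while higher blocks shift and drop cells past the row end.
  This preserves exactly-once coverage, needs zero intra-sweep syncs, and
  keeps all dependencies worker-local, at the cost of gradually unbalancing
  the lowest worker — the price of sync-freedom.  Reverse-strand rows are
  not supported under this plan (strategy selection never picks it with
  revcomp on).

Strategy `auto` picks shifted when revcomp is off, otherwise loopswap for
n < 16 and groupwise for n ≥ 16.  The crossover is a configurable guess:
the available evidence is only that loopswap wins at n = 4 (few very long
sequences) and loses by n = 100.

All strategies produce bit-identical heaps, not merely close ones: every
cell's value is computed by the same arithmetic expression in every plan
(the plans only reorder whole-cell computations), and the heap order is a
total order.  The equivalence tests therefore compare for exact seed/site
agreement with a 1e-9 LLR tolerance as a safety margin.

## Synthetic data

`synth.generate_dataset` plants one motif site per sequence (OOPS) or per
sequence with probability λ (ZOOPS) into i.i.d. background sequence:
uniform background by default, sites drawn from a consensus with
independent per-position corruption (5% default) or from an explicit PWM,
position uniform, optionally reverse-complemented.  Default shape is n = 20
sequences of L = 100 bp with a width-8 site — small enough for exhaustive
oracles, large enough that the planted signal dominates background noise.
`table2_shapes` reproduces the benchmark shape families used for
scalability work (mini-drosoph: 4 ragged sequences of 12,850–297,266 bp,
log-uniform lengths; HS_100/200/400: 100/200/400 × 5,000 bp) at a
configurable length scale; the end-to-end tests and the acceptance script
run them at 1/100 to 1/500 scale (≈0.5–5 kb total) so the whole pipeline
stays in seconds per configuration.

What the generator does **not** emulate: higher-order background
composition, repeats, CpG islands, multiple or overlapping sites, and
length-dependent site placement bias.  Passing recovery tests therefore
demonstrate correctness of the estimator on its own generative model, not
performance on genomic sequence.

## Numerical and interface choices

* Coordinates are 0-based; window starts run over 0 ≤ j ≤ L−W inclusive.
* Non-ACGT letters: configurable strip (default, warns) / seeded
  background replacement / error.  Background: 0-order estimate from the
  input (strand-symmetrized under revcomp) with a 1e-6 per-letter floor,
  overridable by a 4-number file.
* Reverse-strand coordinates are positions on the reverse-complement
  string; `sites.tsv` reports them with an explicit strand column.
* Default width schedule: 7 widths from minw = 8 geometrically spaced by
  ≈√2 up to maxw = 50 (8, 11, 16, 23, 32, 45, 50 before clamping/dedup),
  overridable with explicit `-w` values.
* E-step likelihoods use log-space accumulation with `logsumexp`; ties in
  argmax resolve to the lowest position everywhere.
* P-values saturate at 1 and are floored at the smallest positive double.

## Known limitations

* Single motif per run (no site erasure / multi-motif mode) and no TCM
  (multiple-occurrence) model.
* The χ²-tail P-value is an approximation; it is monotone in the LLR but
  not calibrated across widths, so cross-width comparisons use the EM
  objective, not the P-value.
* Plans are executed serially; the package asserts scheduling-independence
  of the results rather than delivering wall-clock speedup.
* The EM position prior is uniform; no positional bias or site-probability
  smoothing across iterations.
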