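# motifem

De novo DNA motif discovery for sets of unaligned sequences — promoters,
ChIP-derived regions, or any collection suspected to share a transcription
factor binding site.  `motifem` implements the classic two-stage
probabilistic search: an **exhaustive starting-point search** over every
width-W substring, followed by **EM refinement** of the best candidate
models under the OOPS (one occurrence per sequence) or ZOOPS (zero or one
occurrence per sequence) models.  The score sweep — the quadratic hotspot of
the whole search — can be partitioned across logical workers by three
interchangeable plans whose results are provably identical to serial
execution.

## The method

A motif of width *W* is a letter-frequency matrix θ of size |Σ|×(W+1)
(Σ = {A,C,G,T}); column *j* ≥ 1 holds the letter probabilities at motif
position *j* and column 0 the background (non-motif) probabilities.

**Starting-point search.** For every seed window S<sub>i,j</sub> the search
scores every target window with the pair score

    P(S_i,j, S_k,l) = Σ_{p=0..W-1} mat[S_i(j+p)][S_k(l+p)]

where `mat` is a 4×4 letter matrix (by default a log-odds match model,
`mat[a][b] = log2((w·δ(a,b) + (1−w)·bg(a))/bg(a))` with match weight
w = 0.6).  Moving the seed one position right shifts every cell onto a
diagonal predecessor, giving an O(1) update per cell:

    P(S_i,j, S_k,l) = P(S_i,j−1, S_k,l−1) + mat[S_i(j+W−1)][S_k(l+W−1)]
                                          − mat[S_i(j−1)][S_k(l−1)]

with the l = 0 column recomputed directly.  Per seed, the highest-scoring
window of each sequence (and strand, with `-revcomp`) is kept; the sorted
per-sequence maxima are turned into candidate models for each trial
site-count *nsites* (all *n* for OOPS, a doubling grid for ZOOPS), ranked by
the log-likelihood ratio Σ log2(θ[x][p]/bg(x)) of the site set against the
background, with a χ²-tail P-value reported.  The best candidates per
(W, nsites) survive in a bounded, seed-deduplicated heap.

**EM refinement.** Each surviving candidate initializes EM: the E step
computes per-sequence posteriors over site positions (ZOOPS adds a no-site
alternative with prior 1−λ), the M step re-estimates θ and λ from the
expected counts.  The best final log likelihood wins.

**Parallel partitioning.** Three pure plans split the score cells across
workers: `groupwise` (worker groups per seed sequence, one sync per
iteration), `loopswap` (outer loop over position, one sync per position —
best for few long sequences), and `shifted` (blocks slide with the
recurrence diagonal so no intra-sweep sync is needed; single-strand
searches only).  All plans, worker counts and pool weightings yield
bit-identical heaps; this equivalence, plan coverage/disjointness, and the
shifted plan's dependency structure are enforced by tests.

## Worked example

Generate a planted dataset (20 sequences × 100 bp, one slightly corrupted
`GATTACAG` site each) and search it:

```sh
motifem synth --n 20 --length 100 --consensus GATTACAG --corruption 0.05 \
              --seed 11 --out planted.fasta --truth truth.tsv
motifem discover planted.fasta -dna -mod zoops -revcomp -w 8 --oc out
```

which prints

```
wrote 20 sequences (2000 bp), 20 planted sites
W=  8 consensus=GATTACAG loglik=-2695.08 strategy=groupwise
```

— the discovered consensus equals the planted one; `strategy` is the
partition plan auto-selected for this run (groupwise, because `-revcomp`
rules out the shifted plan and n ≥ 16).  `out/motifs.txt` holds the motif
in minimal MEME format:

```
MOTIF GATTACAG MOTIF_1
letter-probability matrix: alength= 4 w= 8 nsites= 20 llr= 159.34 E= 0
 0.001237 0.002226 0.995294 0.001243
 0.946420 0.001266 0.001254 0.051060
 ...
```

(each row is the A/C/G/T probability of one motif column; the first column
is ~100% G, the second ~95% A — the corrupted consensus), `out/sites.tsv`
the MAP site per sequence with strand and coordinates, and
`out/report.json` the run report: strategy, worker plan, score-cell and
synchronization counters (here 6,919,200 cells — exactly (Σ(L−W+1))² for
both strands — and 1,860 syncs), and the fitted λ.

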