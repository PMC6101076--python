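"""Seeded planted-motif dataset generator.

Produces benchmark inputs for the motif search: i.i.d. background sequences
with a motif site planted in each sequence (OOPS) or in a
``occurrence_prob`` fraction of sequences (ZOOPS), optionally on the
reverse strand.  Shapes emulating the published benchmark datasets
(mini-drosoph and the HS_100/200/400 human-promoter sets) are available at
a configurable scale so the same code paths exercise realistic n x L
regimes without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from motifem.seqio import ALPHABET_SIZE, SequenceDataset, decode, encode


@dataclass
class PlantSpec:
    """Recipe for one planted-motif dataset.

    Defaults follow the regime used throughout the test-suite recovery
    studies: 20 sequences of 100 bp with one width-8 site each, 5%
    per-position corruption of the consensus, uniform background.
    """

    n: int = 20
    L: int = 100
    W: int = 8
    consensus: str | None = None
    pwm: np.ndarray | None = None  # 4 x W column-stochastic
    corruption: float = 0.05
    occurrence_prob: float = 1.0
    background: np.ndarray = field(
        default_factory=lambda: np.full(ALPHABET_SIZE, 0.25))
    seed: int = 0
    revcomp_plant: float = 0.0
    lengths: list[int] | None = None  # per-sequence override (ragged sets)

    def __post_init__(self) -> None:
        self.background = np.asarray(self.background, dtype=float)
        for p, name in [(self.corruption, "corruption"),
                        (self.occurrence_prob, "occurrence_prob"),
                        (self.revcomp_plant, "revcomp_plant")]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.pwm is not None:
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.shape != (ALPHABET_SIZE, self.W):
                raise ValueError("pwm must be 4 x W")
            if np.any(np.abs(self.pwm.sum(axis=0) - 1.0) > 1e-9):
                raise ValueError("pwm columns must sum to 1")
        if self.consensus is not None and len(self.consensus) != self.W:
            raise ValueError("consensus length must equal W")
        min_len = min(self.lengths) if self.lengths else self.L
        if self.W > min_len:
            raise ValueError("motif width exceeds sequence length")


def _sample_site(spec: PlantSpec, rng: np.random.Generator,
                 consensus_codes: np.ndarray | None) -> np.ndarray:
    if spec.pwm is not None:
        return np.array([rng.choice(ALPHABET_SIZE, p=spec.pwm[:, p])
                         for p in range(spec.W)], dtype=np.uint8)
    site = consensus_codes.copy()
    hits = rng.random(spec.W) < spec.corruption
    for p in np.nonzero(hits)[0]:
        # mutate to one of the three other letters, uniformly
        site[p] = (site[p] + rng.integers(1, ALPHABET_SIZE)) % ALPHABET_SIZE
    return site


def generate_dataset(
    spec: PlantSpec,
) -> tuple[SequenceDataset, list[tuple[int, int, str]]]:
    """Generate a planted dataset and its truth table.

    Returns the dataset plus a list of ``(sequence_index, position, strand)``
    entries, one per planted site; the position is the 0-based start of the
    (possibly reverse-complemented) site on the forward sequence.  Identical
    seeds give byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    consensus_codes = None
    if spec.pwm is None:
        if spec.consensus is not None:
            consensus_codes = encode(spec.consensus)
        else:
            consensus_codes = rng.integers(
                0, ALPHABET_SIZE, size=spec.W).astype(np.uint8)
    lengths = spec.lengths if spec.lengths is not None else [spec.L] * spec.n
    if spec.lengths is not None and len(lengths) != spec.n:
        raise ValueError("lengths must have n entries")
    seqs: list[str] = []
    truth: list[tuple[int, int, str]] = []
    for i in range(spec.n):
        L = lengths[i]
        codes = rng.choice(ALPHABET_SIZE, size=L,
                           p=spec.background).astype(np.uint8)
        if rng.random() < spec.occurrence_prob:
            site = _sample_site(spec, rng, consensus_codes)
            strand = "+"
            if rng.random() < spec.revcomp_plant:
                site = site[::-1] ^ 3
                strand = "-"
            pos = int(rng.integers(0, L - spec.W + 1))
            codes[pos:pos + spec.W] = site
            truth.append((i, pos, strand))
        seqs.append(decode(codes))
    dataset = SequenceDataset(seqs, background=None,
                              revcomp_enabled=spec.revcomp_plant > 0)
    return dataset, truth


_TABLE2 = {
    # name: (n sequences, min bp, max bp)
    "mini-drosoph": (4, 12850, 297266),
    "HS_100": (100, 5000, 5000),
    "HS_200": (200, 5000, 5000),
    "HS_400": (400, 5000, 5000),
}


def table2_shapes(name: str, scale: float = 1.0, seed: int = 0,
                  W: int = 8, **overrides) -> PlantSpec:
    """A :class:`PlantSpec` matching a named benchmark dataset shape.

    Sequence counts are kept; lengths are scaled by ``scale``.  The
    mini-drosoph set is ragged, so its lengths are drawn log-uniformly
    between the scaled minimum and maximum.
    """
    if name not in _TABLE2:
        raise ValueError(f"unknown dataset name {name!r}; "
                         f"choose from {sorted(_TABLE2)}")
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must be in (0, 1]")
    n, lo, hi = _TABLE2[name]
    lo_s = max(W, int(round(lo * scale)))
    hi_s = max(lo_s, int(round(hi * scale)))
    if lo == hi:
        spec = PlantSpec(n=n, L=lo_s, W=W, seed=seed, **overrides)
    else:
        rng = np.random.default_rng(seed)
        lengths = [int(round(np.exp(rng.uniform(np.log(lo_s), np.log(hi_s)))))
                   for _ in range(n)]
        spec = PlantSpec(n=n, L=max(lengths), W=W, lengths=lengths,
                         seed=seed, **overrides)
    return spec


def write_truth(truth: list[tuple[int, int, str]], path,
                ids: list[str] | None = None) -> None:
    """Truth table as TSV: seq_id, position, strand."""
    with open(path, "w") as fh:
        fh.write("seq_id\tposition\tstrand\n")
        for i, pos, strand in truth:
            sid = ids[i] if ids is not None else f"seq_{i + 1}"
            fh.write(f"{sid}\t{pos}\t{strand}\n")
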