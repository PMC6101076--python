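"""FASTA input, alphabet handling, reverse complements and background.

Sequences live in a :class:`SequenceDataset`: uppercase DNA strings over
``A,C,G,T`` plus per-sequence identifiers, a 0-order background letter
frequency vector, and (optionally) precomputed reverse complements for
double-stranded search.  Substring start positions are 0-based; a width-W
window may start at ``0 <= j <= L_i - W`` inclusive.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
ALPHABET_SIZE = 4

#: default per-letter floor applied to estimated backgrounds (avoids log(0))
BACKGROUND_FLOOR = 1e-6

_CODE = {c: i for i, c in enumerate(ALPHABET)}
_COMP_TABLE = str.maketrans("ACGT", "TGCA")

# byte-value -> code lookup (255 marks a non-DNA byte)
_BYTE_CODE = np.full(256, 255, dtype=np.uint8)
for _c, _i in _CODE.items():
    _BYTE_CODE[ord(_c)] = _i


def encode(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string as a uint8 code array (A=0,C=1,G=2,T=3)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _BYTE_CODE[raw]
    if codes.size and codes.max() == 255:
        bad = seq[int(np.argmax(codes == 255))]
        raise ValueError(f"non-DNA residue {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string; raises on non-ACGT residues."""
    for c in seq:
        if c not in _CODE:
            raise ValueError(f"non-DNA residue {c!r} in sequence")
    return seq.translate(_COMP_TABLE)[::-1]


@dataclass
class SequenceDataset:
    """An input set of DNA sequences S = {S_1..S_n} with its background.

    Parameters
    ----------
    sequences
        Uppercase DNA strings over ``ACGT``; every length must be >= 1.
    ids
        Per-sequence identifiers; generated as ``seq_1..seq_n`` if omitted.
    background
        Length-4 frequency vector in A,C,G,T order.  Estimated from the
        dataset (0-order, with a small per-letter floor) if omitted.
    revcomp_enabled
        When true, reverse complements are searched too and the estimated
        background is strand-symmetrized (freq(A)=freq(T), freq(C)=freq(G)).
    """

    sequences: list[str]
    ids: list[str] | None = None
    background: np.ndarray | None = None
    revcomp_enabled: bool = False

    _codes: list[np.ndarray] = field(default_factory=list, repr=False,
                                     init=False, compare=False)
    _rc_codes: list[np.ndarray] = field(default_factory=list, repr=False,
                                        init=False, compare=False)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("dataset must contain at least one sequence")
        if self.ids is None:
            self.ids = [f"seq_{i + 1}" for i in range(len(self.sequences))]
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences length mismatch")
        self._codes = []
        for s in self.sequences:
            if len(s) < 1:
                raise ValueError("empty sequence in dataset")
            self._codes.append(encode(s))
        self._rc_codes = [c[::-1] ^ 3 for c in self._codes]  # A<->T, C<->G
        if self.background is None:
            self.background = background_frequencies(self)
        else:
            self.background = np.asarray(self.background, dtype=float)
            if self.background.shape != (ALPHABET_SIZE,):
                raise ValueError("background must have 4 entries (A,C,G,T)")
            if abs(float(self.background.sum()) - 1.0) > 1e-9:
                raise ValueError("background frequencies must sum to 1")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def lengths(self) -> list[int]:
        return [len(s) for s in self.sequences]

    @property
    def total_bp(self) -> int:
        return sum(self.lengths)

    @property
    def codes(self) -> list[np.ndarray]:
        return self._codes

    @property
    def rc_codes(self) -> list[np.ndarray]:
        """Codes of the reverse complement of each sequence."""
        return self._rc_codes

    def rc_sequences(self) -> list[str]:
        return [decode(c) for c in self._rc_codes]

    def n_positions(self, i: int, W: int) -> int:
        """Number of width-W window starts in sequence i (L_i - W + 1)."""
        return len(self.sequences[i]) - W + 1


def background_frequencies(
    dataset: SequenceDataset | list[str],
    revcomp: bool | None = None,
    floor: float = BACKGROUND_FLOOR,
) -> np.ndarray:
    """0-order background letter frequencies of a dataset.

    With ``revcomp`` on, counts are averaged with the reverse-complement
    counts, which forces freq(A)=freq(T) and freq(C)=freq(G).  A per-letter
    floor keeps every frequency strictly positive; the result sums to 1.
    """
    if isinstance(dataset, SequenceDataset):
        seqs = dataset.sequences
        if revcomp is None:
            revcomp = dataset.revcomp_enabled
    else:
        seqs = list(dataset)
        revcomp = bool(revcomp)
    total = sum(len(s) for s in seqs)
    if total == 0:
        raise ValueError("cannot estimate background from zero total length")
    counts = np.zeros(ALPHABET_SIZE, dtype=float)
    for s in seqs:
        counts += np.bincount(encode(s), minlength=ALPHABET_SIZE)
    if revcomp:
        counts = (counts + counts[::-1]) / 2.0  # A<->T, C<->G under reversal
    freq = counts / counts.sum()
    freq = np.maximum(freq, floor)
    return freq / freq.sum()


def _sanitize(seq: str, policy: str, rng: np.random.Generator | None,
              background: np.ndarray | None, record_id: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = [c for c in set(seq) if c not in _CODE]
    if not bad:
        return seq
    if policy == "error":
        raise ValueError(f"record {record_id}: non-DNA residues {sorted(bad)}")
    if policy == "strip":
        logger.warning(
            "record %s: stripping %d non-ACGT residues",
            record_id, sum(seq.count(c) for c in bad),
        )
        return "".join(c for c in seq if c in _CODE)
    if policy == "replace":
        if rng is None:
            rng = np.random.default_rng(0)
        bg = background if background is not None else np.full(4, 0.25)
        out = [
            c if c in _CODE else ALPHABET[rng.choice(ALPHABET_SIZE, p=bg)]
            for c in seq
        ]
        logger.warning("record %s: replaced non-ACGT residues from background",
                       record_id)
        return "".join(out)
    raise ValueError(f"unknown ambiguity policy {policy!r}")


def read_fasta(
    path,
    ambiguity: str = "strip",
    revcomp: bool = False,
    background: np.ndarray | None = None,
    seed: int | None = None,
) -> SequenceDataset:
    """Read a multi-record FASTA file into a :class:`SequenceDataset`.

    ``ambiguity`` controls non-ACGT letters: ``strip`` (default, with a
    warning), ``replace`` (seeded sample from the background), or ``error``.
    Duplicate record ids are kept but suffixed with ``_2``, ``_3``, ...
    """
    rng = np.random.default_rng(seed) if seed is not None else None
    ids: list[str] = []
    seqs: list[str] = []
    seen: Counter[str] = Counter()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _sanitize(str(rec.seq), ambiguity, rng, background, rec.id)
        if not seq:
            raise ValueError(f"record {rec.id} is empty after sanitization")
        seen[rec.id] += 1
        if seen[rec.id] > 1:
            new_id = f"{rec.id}_{seen[rec.id]}"
            logger.warning("duplicate id %s renamed to %s", rec.id, new_id)
            ids.append(new_id)
        else:
            ids.append(rec.id)
        seqs.append(seq)
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return SequenceDataset(seqs, ids=ids, background=background,
                           revcomp_enabled=revcomp)


def read_background(path) -> np.ndarray:
    """Read 4 whitespace-separated floats (A,C,G,T order) as a background."""
    vals = np.loadtxt(str(path), dtype=float).ravel()
    if vals.size != ALPHABET_SIZE:
        raise ValueError("background file must contain exactly 4 numbers")
    if np.any(vals < 0) or abs(float(vals.sum()) - 1.0) > 1e-6:
        raise ValueError("background must be non-negative and sum to 1")
    return vals / vals.sum()


def write_fasta(dataset: SequenceDataset, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(dataset.ids, dataset.sequences):
            fh.write(f">{sid}\n")
            for off in range(0, len(seq), width):
                fh.write(seq[off:off + width] + "\n")
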