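import numpy as np
import pytest

from motifem.seqio import SequenceDataset

LETTERS = np.array(list("ACGT"))


def random_sequences(rng, n, lmin, lmax):
    return ["".join(rng.choice(LETTERS, size=rng.integers(lmin, lmax + 1)))
            for _ in range(n)]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def make_dataset(rng):
    """Factory for small random datasets: make_dataset(n, lmin, lmax, revcomp)."""

    def _make(n=3, lmin=15, lmax=30, revcomp=False, seed=None):
        local = np.random.default_rng(seed) if seed is not None else rng
        return SequenceDataset(random_sequences(local, n, lmin, lmax),
                               revcomp_enabled=revcomp)

    return _make
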