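import numpy as np
import pytest

from morf import GenotypeDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20121203)


@pytest.fixture
def make_dataset():
    """Factory for small random two-class genotype datasets."""

    def _make(n=12, a=6, seed=0, p=(0.5, 0.3, 0.2)):
        rng = np.random.default_rng(seed)
        X = rng.choice([0, 1, 2], size=(n, a), p=p)
        y = np.zeros(n, dtype=int)
        y[n // 2 :] = 1
        rng.shuffle(y)
        if len(np.unique(y)) < 2:  # n == 2 edge case
            y = np.array([0, 1])
        return GenotypeDataset(X, y)

    return _make


@pytest.fixture
def xor_dataset():
    """Fully penetrant XOR toy: class = parity of the two attributes."""
    X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
    y = np.array([0, 1, 1, 0])
    return GenotypeDataset(X, y)
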