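import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from epifst import GenotypeDataset, PairCounts


@pytest.fixture
def rng():
    return np.random.default_rng(20110)


@pytest.fixture
def tiny_dataset():
    """Four subjects, two SNPs, two cases / two controls."""
    geno = np.array([[0, 2], [1, 1], [2, 0], [0, 0]], dtype=float)
    return GenotypeDataset(["rs1", "rs2"], geno, np.array([1, 1, 0, 0]))


def random_pair_counts(rng, n_cases=200, n_controls=200) -> PairCounts:
    """Random non-degenerate 3x3x2 tensor with polymorphic loci."""
    for _ in range(100):
        probs = rng.dirichlet(np.ones(9))
        tensor = np.stack([
            rng.multinomial(n_controls, probs).reshape(3, 3),
            rng.multinomial(n_cases, probs).reshape(3, 3),
        ], axis=2)
        pooled = tensor.sum(axis=2)
        dos = np.arange(3)
        pa = (pooled.sum(1) * dos).sum() / (2 * pooled.sum())
        pb = (pooled.sum(0) * dos).sum() / (2 * pooled.sum())
        if 0 < pa < 1 and 0 < pb < 1:
            return PairCounts(tensor)
    raise AssertionError("could not draw polymorphic counts")
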