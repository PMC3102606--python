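import numpy as np
import pytest

from rme.matrix import MutationMatrix


def make_matrix(rows, samples=None, genes=None, n_universe=None):
    """Small-matrix builder used across the suite."""
    values = np.asarray(rows, dtype=np.int8)
    k, n = values.shape
    samples = samples or [f"s{i}" for i in range(k)]
    genes = genes or [f"g{j}" for j in range(n)]
    return MutationMatrix(samples, genes, values, n_universe=n_universe)


@pytest.fixture
def tiny_matrix():
    """4 samples x 3 genes with a mutually exclusive pair (gA, gB)."""
    return make_matrix(
        [
            [1, 0, 0],
            [1, 0, 1],
            [0, 1, 0],
            [0, 1, 1],
        ],
        samples=["s1", "s2", "s3", "s4"],
        genes=["gA", "gB", "gC"],
    )
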