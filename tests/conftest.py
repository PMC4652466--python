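import numpy as np
import pytest

from otuclubs.io_abundance import AbundanceMatrix
from tests_helpers import make_network_from_masked


@pytest.fixture
def small_matrix() -> AbundanceMatrix:
    """3 samples x 4 OTUs with two groups."""
    counts = np.array(
        [
            [10, 0, 5, 3],
            [2, 7, 0, 1],
            [4, 4, 4, 4],
        ]
    )
    return AbundanceMatrix(
        ["s1", "s2", "s3"],
        ["Prevotella", "Streptococcus", "Veillonella", "Rothia"],
        counts,
        {"s1": "smoker", "s2": "former", "s3": "smoker"},
    )


@pytest.fixture
def two_block_net():
    """Two positive 4-blocks (r = 0.6) with no cross edges."""
    m = np.zeros((8, 8))
    for base in (0, 4):
        for i in range(4):
            for j in range(i + 1, 4):
                m[base + i, base + j] = m[base + j, base + i] = 0.6
    net, corr = make_network_from_masked(m)
    return net, corr, m
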