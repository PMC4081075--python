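import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20140528)


@pytest.fixture
def small_genes():
    """A handful of gene models on both strands for assignment tests."""
    from cofbal.cistrome import GeneModel

    return [
        GeneModel("g1", "g1", "chr1", "+", 100_000, 100_000, 110_000),
        GeneModel("g2", "g2", "chr1", "-", 219_999, 200_000, 220_000),
        GeneModel("g3", "g3", "chr2", "+", 50_000, 50_000, 52_000),
    ]
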