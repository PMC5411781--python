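import numpy as np
import pytest

from pcfkit import simdata


@pytest.fixture
def rng():
    return np.random.default_rng(20_170_501)


@pytest.fixture
def tiny_ancestor():
    """Two 500-kb chromosomes, one msHSB each — small enough for
    per-base oracles."""
    return simdata.AncestorGenome(
        chromosomes=[("A", 500_000), ("B", 500_000)],
        mshsb_intervals=[("A", 150_000, 350_000), ("B", 100_000, 300_000)],
    )


@pytest.fixture
def desk_ancestor():
    """The 5-chromosome, 20-Mb desk-scale ancestor."""
    return simdata.default_ancestor()
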