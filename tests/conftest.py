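import numpy as np
import pytest

from kinscape import Lattice, truncated_binomial_kernel


@pytest.fixture
def ring9():
    return Lattice([9])


@pytest.fixture
def ring9_kernel(ring9):
    return truncated_binomial_kernel(ring9, 0.6, 1.8)


@pytest.fixture
def torus6():
    return Lattice([2, 3])


@pytest.fixture
def rng():
    return np.random.default_rng(20240530)
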