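import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from jointmds import DistMatrix, FixtureSpec, Structure, make_structure


@pytest.fixture
def helix20() -> Structure:
    return make_structure(FixtureSpec(n_loci=20, seed=0))


@pytest.fixture
def helix100() -> Structure:
    return make_structure(FixtureSpec(n_loci=100, seed=0))


def exact_distmatrix(structure: Structure) -> DistMatrix:
    """Exact Euclidean target distances of a structure (no missing pairs)."""
    delta = squareform(pdist(structure.coords))
    return DistMatrix(structure.chrom, structure.bin_size, structure.bins.copy(), delta)


@pytest.fixture
def helix20_delta(helix20) -> DistMatrix:
    return exact_distmatrix(helix20)


@pytest.fixture
def helix100_delta(helix100) -> DistMatrix:
    return exact_distmatrix(helix100)


def random_structure(n: int, seed: int) -> np.ndarray:
    return np.random.default_rng(seed).normal(size=(n, 3))
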