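import numpy as np
import pytest

from ensrep import MixtureSpec, StateVector, build_sector_basis
from ensrep.fock import so


@pytest.fixture
def occ_1122():
    return [so(1, "alpha"), so(1, "beta"), so(2, "alpha"), so(2, "beta")]


@pytest.fixture
def occ_1132():
    return [so(1, "alpha"), so(1, "beta"), so(3, "alpha"), so(2, "beta")]


@pytest.fixture
def occ_1133():
    return [so(1, "alpha"), so(1, "beta"), so(3, "alpha"), so(3, "beta")]


@pytest.fixture
def mix_4e4o(occ_1122, occ_1132):
    """Equal-weight single-substitution mixture on 8 spin-orbitals."""
    return MixtureSpec.two_state(occ_1122, occ_1132, 0.5)


@pytest.fixture
def mix_4e3o(occ_1122, occ_1133):
    """Equal-weight double-substitution mixture on 6 spin-orbitals."""
    return MixtureSpec.two_state(occ_1122, occ_1133, 0.5)


def random_state(basis, seed=0):
    rng = np.random.default_rng(seed)
    amp = rng.normal(size=basis.dim) + 1j * rng.normal(size=basis.dim)
    return StateVector(basis, amp).normalized()


@pytest.fixture
def random_4e8so():
    return random_state(build_sector_basis(8, 0, 4, 0), seed=42)
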