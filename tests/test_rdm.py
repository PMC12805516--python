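"""RDM construction, distances, contraction, audits, noise and I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ensrep import (
    ReducedDensityMatrix,
    add_noise,
    build_sector_basis,
    coleman_check,
    compute_rdm,
    contract_2rdm,
    hs_distance_sq,
    mixture_target,
    purify_mixture,
    slater_determinant,
)
from ensrep.rdm import distance_state_gradient
from ensrep.fock import so
from ensrep.states import MixtureSpec
from tests.conftest import random_state


def test_determinant_1rdm_is_occupation_diagonal(occ_1122):
    basis = build_sector_basis(8, 0, 4, 0)
    rdm = compute_rdm(slater_determinant(basis, occ_1122), 1)
    assert np.allclose(rdm.matrix, np.diag([1, 1, 1, 1, 0, 0, 0, 0]))


def test_rdm_traces_follow_normalization(random_4e8so):
    assert compute_rdm(random_4e8so, 1).trace == pytest.approx(4.0, abs=1e-10)
    assert compute_rdm(random_4e8so, 2).trace == pytest.approx(12.0, abs=1e-10)


def test_unsupported_order_rejected(random_4e8so):
    with pytest.raises(ValueError, match="p must be 1 or 2"):
        compute_rdm(random_4e8so, 3)


def test_rdm_is_hermitian_and_positive(random_4e8so):
    for p in (1, 2):
        m = compute_rdm(random_4e8so, p).matrix
        assert np.abs(m - m.conj().T).max() < 1e-10
        assert np.linalg.eigvalsh(m).min() > -1e-10


def test_1rdm_eigenvalues_respect_pauli_bound(random_4e8so):
    lam = compute_rdm(random_4e8so, 1).eigenvalues()
    assert lam.min() > -1e-10 and lam.max() < 1 + 1e-10


def test_2rdm_antisymmetry(random_4e8so):
    M = 8
    G = compute_rdm(random_4e8so, 2).matrix.reshape(M, M, M, M)
    assert np.abs(G - -G.transpose(1, 0, 2, 3)).max() < 1e-12
    assert np.abs(G - -G.transpose(0, 1, 3, 2)).max() < 1e-12
    ii = np.arange(M)
    assert np.abs(G[ii, ii]).max() == 0.0


def test_mixture_eigenvalues_table(mix_4e4o, mix_4e3o):
    lam = mixture_target(mix_4e4o, 1, 8).eigenvalues()
    assert np.allclose(lam, [1, 1, 1, 0.5, 0.5, 0, 0, 0], atol=1e-12)
    lam = mixture_target(mix_4e3o, 1, 6).eigenvalues()
    assert np.allclose(lam, [1, 1, 0.5, 0.5, 0.5, 0.5], atol=1e-12)


def test_mixture_target_linear_in_weight(occ_1122, occ_1132):
    for p in (1, 2):
        t0 = mixture_target(MixtureSpec.two_state(occ_1122, occ_1132, 0.0), p, 8)
        t1 = mixture_target(MixtureSpec.two_state(occ_1122, occ_1132, 1.0), p, 8)
        tw = mixture_target(MixtureSpec.two_state(occ_1122, occ_1132, 0.3), p, 8)
        assert np.abs(tw.matrix - (0.3 * t1.matrix + 0.7 * t0.matrix)).max() < 1e-14


@pytest.mark.parametrize("p", [1, 2])
def test_purified_mixture_reproduces_target(mix_4e4o, p):
    """An orthonormal-bath-tag purification has the same system p-RDM as the mixture."""
    target = mixture_target(mix_4e4o, p, 8)
    psi = purify_mixture(mix_4e4o, 8)
    assert np.abs(compute_rdm(psi, p).matrix - target.matrix).max() < 1e-12


def test_distance_basics(random_4e8so):
    a = compute_rdm(random_4e8so, 1)
    b = compute_rdm(random_state(random_4e8so.basis, 5), 1)
    assert hs_distance_sq(a, a) == 0.0
    assert hs_distance_sq(a, b) == pytest.approx(hs_distance_sq(b, a), abs=1e-14)
    assert hs_distance_sq(a, b) > 0


def test_distance_of_substituted_determinants(occ_1122, occ_1132):
    """One spin-orbital substitution flips two occupations: squared distance 2."""
    basis = build_sector_basis(8, 0, 4, 0)
    a = compute_rdm(slater_determinant(basis, occ_1122), 1)
    b = compute_rdm(slater_determinant(basis, occ_1132), 1)
    assert hs_distance_sq(a, b) == pytest.approx(2.0, abs=1e-14)


def test_distance_invariant_under_common_orbital_rotation(random_4e8so):
    rng = np.random.default_rng(3)
    a = compute_rdm(random_4e8so, 1).matrix
    b = compute_rdm(random_state(random_4e8so.basis, 6), 1).matrix
    q, _ = np.linalg.qr(rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8)))
    ra = ReducedDensityMatrix(1, 8, 4, q @ a @ q.conj().T)
    rb = ReducedDensityMatrix(1, 8, 4, q @ b @ q.conj().T)
    d0 = np.sum(np.abs(a - b) ** 2)
    assert hs_distance_sq(ra, rb) == pytest.approx(d0, abs=1e-10)


def test_distance_shape_mismatch():
    a = ReducedDensityMatrix(1, 8, 4, np.eye(8) / 2)
    b = ReducedDensityMatrix(1, 6, 4, np.eye(6) / 2)
    with pytest.raises(ValueError):
        hs_distance_sq(a, b)


def test_contraction_of_determinant_2rdm(occ_1122):
    basis = build_sector_basis(8, 0, 4, 0)
    det = slater_determinant(basis, occ_1122)
    contracted = contract_2rdm(compute_rdm(det, 2))
    assert np.abs(contracted.matrix - compute_rdm(det, 1).matrix).max() < 1e-12
    assert contracted.trace == pytest.approx(4.0)


def test_contraction_matches_1rdm_for_random_states(random_4e8so):
    c = contract_2rdm(compute_rdm(random_4e8so, 2))
    assert np.abs(c.matrix - compute_rdm(random_4e8so, 1).matrix).max() < 1e-10


def test_contraction_commutes_with_mixing(occ_1122, occ_1133):
    mix = MixtureSpec.two_state(occ_1122, occ_1133, 0.5)
    c = contract_2rdm(mixture_target(mix, 2, 8))
    assert np.abs(c.matrix - mixture_target(mix, 1, 8).matrix).max() < 1e-12


def test_coleman_accepts_valid_spectrum(mix_4e4o):
    report = coleman_check(mixture_target(mix_4e4o, 1, 8))
    assert report.coleman_pass
    assert np.allclose(report.eigenvalues, [1, 1, 1, 0.5, 0.5, 0, 0, 0])


def test_coleman_rejects_bad_eigenvalue_and_trace():
    bad = ReducedDensityMatrix(1, 4, 4, np.diag([1.2, 1.0, 0.9, 0.9]))
    report = coleman_check(bad)
    assert not report.coleman_pass
    assert any("lambda" in label for label, _ in report.violations)
    short = ReducedDensityMatrix(1, 4, 4, np.diag([1.0, 1.0, 1.0, 0.5]))
    assert not coleman_check(short).coleman_pass


def test_noise_zero_eps_is_bit_identical(mix_4e4o):
    t = mixture_target(mix_4e4o, 1, 8)
    assert np.array_equal(add_noise(t, 0.0, 7).matrix, t.matrix)


def test_noise_deterministic_per_seed(mix_4e4o):
    t = mixture_target(mix_4e4o, 1, 8)
    a = add_noise(t, 0.1, 11)
    b = add_noise(t, 0.1, 11)
    c = add_noise(t, 0.1, 12)
    assert np.array_equal(a.matrix, b.matrix)
    assert not np.array_equal(a.matrix, c.matrix)
    with pytest.raises(ValueError):
        add_noise(t, -0.1, 0)


def test_noise_scale_matches_uniform_moments(mix_4e4o):
    """Monte-Carlo check of E||eps R||^2 for Hermitized uniform noise.

    Diagonal entries keep variance 1/3; off-diagonal Hermitized entries are
    the mean of two independent uniforms (variance 1/6).
    """
    t = mixture_target(mix_4e4o, 1, 8)
    d = 8
    eps = 0.05
    draws = 4000
    norms = [
        np.sum(np.abs(add_noise(t, eps, s).matrix - t.matrix) ** 2)
        for s in range(draws)
    ]
    expected = eps**2 * (d / 3.0 + (d * d - d) / 6.0)
    assert np.mean(norms) == pytest.approx(expected, rel=0.05)


def test_raw_noise_keeps_antihermitian_part(mix_4e4o):
    t = mixture_target(mix_4e4o, 1, 8)
    raw = add_noise(t, 0.1, 3, hermitize=False).matrix
    assert np.abs(raw - raw.conj().T).max() > 1e-3


@given(seed=st.integers(0, 10), p=st.sampled_from([1, 2]))
@settings(max_examples=10, deadline=None, derandomize=True)
def test_gradient_matches_finite_differences(seed, p):
    from ensrep.pool import build_pool, pool_gradients
    from ensrep.fock import apply_exponential

    basis = build_sector_basis(6, 0, 3, 0)
    psi = random_state(basis, seed)
    target = compute_rdm(random_state(basis, seed + 100), p)
    pool = build_pool(basis)
    grads = pool_gradients(pool, psi, target)
    assert np.abs(np.imag(grads)).max() == 0.0  # gradients are real by construction
    h = 1e-5
    for m in range(0, len(pool), max(1, len(pool) // 7)):
        dp = hs_distance_sq(compute_rdm(apply_exponential(pool[m], h, psi), p), target)
        dm = hs_distance_sq(compute_rdm(apply_exponential(pool[m], -h, psi), p), target)
        assert grads[m] == pytest.approx((dp - dm) / (2 * h), abs=1e-6)


def test_gradient_zero_at_exact_minimum(random_4e8so):
    from ensrep.pool import build_pool, pool_gradients

    target = compute_rdm(random_4e8so, 1)
    grads = pool_gradients(build_pool(random_4e8so.basis), random_4e8so, target)
    assert np.abs(grads).max() < 1e-10


def test_rdm_file_roundtrip(tmp_path, mix_4e4o):
    t = mixture_target(mix_4e4o, 2, 8)
    text = tmp_path / "target.rdm"
    t.save(text)
    loaded = ReducedDensityMatrix.load(text)
    assert (loaded.p, loaded.M_sys, loaded.N) == (2, 8, 4)
    assert np.abs(loaded.matrix - t.matrix).max() == 0.0
    binary = tmp_path / "target.npy"
    t.save(binary)
    loaded = ReducedDensityMatrix.load(binary)
    assert np.array_equal(loaded.matrix, t.matrix)


def test_klyachko_audit_on_determinant_and_mixture(mix_4e4o, occ_1122):
    from ensrep import bundled_inequalities, build_sector_basis, klyachko_check, slater_determinant

    ineqs = bundled_inequalities(4, 8)
    basis = build_sector_basis(8, 0, 4, 0)
    det_rdm = compute_rdm(slater_determinant(basis, occ_1122), 1)
    report = klyachko_check(det_rdm, ineqs)
    # a determinant is pure-representable: every constraint holds
    assert report.klyachko_satisfied == report.klyachko_total == 15
    assert report.violations == []

    mixed = klyachko_check(mixture_target(mix_4e4o, 1, 8), ineqs)
    assert mixed.klyachko_satisfied < mixed.klyachko_total
    assert len(mixed.violations) == mixed.klyachko_total - mixed.klyachko_satisfied
    assert all(margin < 0 for _, margin in mixed.violations)


def test_klyachko_padding_and_dimension_errors():
    from ensrep import bundled_inequalities, klyachko_check

    ineqs = bundled_inequalities(4, 8)
    six = ReducedDensityMatrix(1, 6, 4, np.diag([1, 1, 0.5, 0.5, 0.5, 0.5]))
    assert klyachko_check(six, ineqs).klyachko_satisfied == 15  # zero-padded
    wrong_n = ReducedDensityMatrix(1, 8, 3, np.diag([1, 1, 1, 0, 0, 0, 0, 0.0]))
    with pytest.raises(ValueError, match="N = 4"):
        klyachko_check(wrong_n, ineqs)
    too_big = ReducedDensityMatrix(1, 10, 4, np.eye(10) * 0.4)
    with pytest.raises(ValueError, match="spin-orbitals"):
        klyachko_check(too_big, ineqs)


def test_inequality_file_roundtrip(tmp_path):
    from ensrep import load_inequalities

    path = tmp_path / "toy.txt"
    path.write_text("3 6\n1 0 0 0 0 0 <= 1\n0 0 0 1 -1 -1 <= 0\n")
    s = load_inequalities(path)
    assert (s.N, s.M, len(s)) == (3, 6, 2)
    assert s.consts.tolist() == [1.0, 0.0]
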