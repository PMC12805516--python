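"""Molecular integrals, sector Hamiltonians, canonical thermal targets."""

from itertools import combinations

import numpy as np
import pytest

from ensrep import build_sector_basis, coleman_check
from ensrep.integrals import (
    MolecularIntegrals,
    _ao_integrals,
    hydrogen_chain,
    read_fcidump,
    sto3g_hydrogen_integrals,
    write_fcidump,
)
from ensrep.thermal import (
    ThermalSpec,
    build_hamiltonian,
    diagonalize_sector,
    resolve_kt,
    thermal_rdm,
)

# Classic published STO-3G H2 values at R = 1.4 bohr (4-decimal precision)
R14_ANGSTROM = 1.4 / 1.8897259886


def test_ao_integrals_match_published_h2_values():
    S, T, V, eri = _ao_integrals(np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.4]]))
    assert S[0, 1] == pytest.approx(0.6593, abs=2e-4)
    assert T[0, 0] == pytest.approx(0.7600, abs=2e-4)
    assert T[0, 1] == pytest.approx(0.2365, abs=2e-4)
    assert eri[0, 0, 0, 0] == pytest.approx(0.7746, abs=2e-4)
    assert eri[0, 0, 1, 1] == pytest.approx(0.5697, abs=2e-4)
    assert eri[0, 0, 0, 1] == pytest.approx(0.4441, abs=2e-4)
    assert eri[0, 1, 0, 1] == pytest.approx(0.2970, abs=2e-4)


def test_h2_fci_ground_energy_matches_literature():
    """Full diagonalization at R = 1.4 bohr: E_0 = -1.13728 Hartree."""
    ints = sto3g_hydrogen_integrals([[0, 0, 0], [0, 0, R14_ANGSTROM]], 2)
    basis = build_sector_basis(4, 0, 2, 0)
    E, _ = diagonalize_sector(build_hamiltonian(ints, basis), basis)
    assert E[0] + ints.core_energy == pytest.approx(-1.13728, abs=2e-5)
    # mean-field reference determinant energy
    H = build_hamiltonian(ints, basis)
    assert H[0, 0] + ints.core_energy == pytest.approx(-1.1167, abs=2e-4)


def test_hamiltonian_hermitian_and_number_conserving():
    ints = hydrogen_chain(3, 0.75)
    basis = build_sector_basis(6, 0, 3, 0)
    H = build_hamiltonian(ints, basis)
    assert np.abs(H - H.T).max() < 1e-10


def _slater_condon_oracle(ints: MolecularIntegrals, basis):
    """Independent dense Hamiltonian from determinant-pair rules."""
    h1 = ints.spin_orbital_h()
    v = ints.spin_orbital_v()
    M = basis.M_sys
    dets = [tuple(g for g in range(M) if int(w) & (1 << g)) for w in basis.states]
    dim = len(dets)
    H = np.zeros((dim, dim))
    for a, da in enumerate(dets):
        sa = set(da)
        for b, db in enumerate(dets):
            sb = set(db)
            diff = sorted(sa - sb)
            diffb = sorted(sb - sa)
            if len(diff) == 0:
                H[a, b] = sum(h1[p, p] for p in da) + 0.5 * sum(
                    v[p, q, p, q] for p in da for q in da
                )
            elif len(diff) == 1:
                p, q = diff[0], diffb[0]
                sgn = (-1) ** (da.index(p) + db.index(q))
                H[a, b] = sgn * (h1[p, q] + sum(v[p, r, q, r] for r in sa & sb))
            elif len(diff) == 2:
                p, q = diff
                r, s_ = diffb
                sgn = (-1) ** (da.index(p) + da.index(q) + db.index(r) + db.index(s_))
                H[a, b] = sgn * v[p, q, r, s_]
    return H


@pytest.mark.parametrize("n_atoms,spacing", [(2, 0.75), (3, 1.5)])
def test_hamiltonian_matches_slater_condon_oracle(n_atoms, spacing):
    ints = hydrogen_chain(n_atoms, spacing)
    basis = build_sector_basis(2 * n_atoms, 0, n_atoms, 0)
    H = build_hamiltonian(ints, basis)
    oracle = _slater_condon_oracle(ints, basis)
    E = np.linalg.eigvalsh(H)
    E_oracle = np.linalg.eigvalsh(oracle)
    assert np.abs(E - E_oracle).max() < 1e-9


def test_two_electron_term_vanishes_without_repulsion():
    ints = hydrogen_chain(2, 0.75)
    free = MolecularIntegrals(
        ints.K, 2, ints.h, np.zeros_like(ints.eri), ints.core_energy
    )
    basis = build_sector_basis(4, 0, 2, 0)
    E, _ = diagonalize_sector(build_hamiltonian(free, basis), basis)
    eps = np.linalg.eigvalsh(ints.h)
    expected = sorted(eps[i] + eps[j] for i in range(2) for j in range(2)) + [
        2 * eps[0], 2 * eps[1]
    ]
    # one-body spectrum: all sums of two (spin-degenerate) orbital energies
    pair_sums = sorted(
        eps[p // 2] + eps[q // 2] for p, q in combinations(range(4), 2)
    )
    assert np.allclose(sorted(E), pair_sums, atol=1e-10)


def test_eigenpairs_reconstruct():
    ints = hydrogen_chain(3, 0.75)
    basis = build_sector_basis(6, 0, 3, 0)
    H = build_hamiltonian(ints, basis)
    E, V = diagonalize_sector(H, basis)
    assert np.abs(H @ V - V * E).max() < 1e-9
    assert np.abs(V.T @ V - np.eye(len(E))).max() < 1e-10


def test_h3_levels_have_even_sz_degeneracy():
    """Every level of the 3-electron sector appears evenly across Sz = +-1/2."""
    ints = hydrogen_chain(3, 0.75)
    basis = build_sector_basis(6, 0, 3, 0)
    E, _ = diagonalize_sector(build_hamiltonian(ints, basis), basis)
    levels = []
    for e in E:
        if not levels or e > levels[-1][0] + 1e-8:
            levels.append([e, 1])
        else:
            levels[-1][1] += 1
    assert all(count % 2 == 0 for _, count in levels)


def test_spectrum_invariant_under_orbital_rotation():
    ints = hydrogen_chain(3, 0.75)
    rng = np.random.default_rng(0)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    rotated = MolecularIntegrals(
        3, 3,
        q.T @ ints.h @ q,
        np.einsum("abcd,ap,bq,cr,ds->pqrs", ints.eri, q, q, q, q),
        ints.core_energy,
    )
    basis = build_sector_basis(6, 0, 3, 0)
    E1, _ = diagonalize_sector(build_hamiltonian(ints, basis), basis)
    E2, _ = diagonalize_sector(build_hamiltonian(rotated, basis), basis)
    assert np.abs(E1 - E2).max() < 1e-9


def test_gap_temperature_rule_skips_degenerate_ground_multiplet():
    ints = hydrogen_chain(3, 0.75)
    basis = build_sector_basis(6, 0, 3, 0)
    E, _ = diagonalize_sector(build_hamiltonian(ints, basis), basis)
    kt = resolve_kt(ThermalSpec(ints), E)
    assert kt > 1e-3  # the ground doublet's zero gap is not used
    assert kt == pytest.approx(E[2] - E[0], abs=1e-10)
    with pytest.raises(ValueError, match="explicit"):
        resolve_kt(ThermalSpec(ints), np.zeros(5))


def test_thermal_low_temperature_limit_is_ground_multiplet_average():
    ints = hydrogen_chain(3, 1.5)
    cold = thermal_rdm(ThermalSpec(ints, temperature_rule="explicit", kT=1e-5, p=1))
    basis = build_sector_basis(6, 0, 3, 0)
    E, V = diagonalize_sector(build_hamiltonian(ints, basis), basis)
    from ensrep import StateVector, compute_rdm

    ground = [
        compute_rdm(StateVector(basis, V[:, i]), 1).matrix
        for i in range(len(E)) if E[i] < E[0] + 1e-8
    ]
    assert np.abs(cold.matrix - np.mean(ground, axis=0)).max() < 1e-10


def test_thermal_high_temperature_limit_is_uniform_average():
    ints = hydrogen_chain(2, 0.75)
    hot = thermal_rdm(ThermalSpec(ints, temperature_rule="explicit", kT=1e9, p=1))
    basis = build_sector_basis(4, 0, 2, 0)
    E, V = diagonalize_sector(build_hamiltonian(ints, basis), basis)
    from ensrep import StateVector, compute_rdm

    avg = np.mean(
        [compute_rdm(StateVector(basis, v), 1).matrix for v in V.T], axis=0
    )
    assert np.abs(hot.matrix - avg).max() < 1e-8


def test_thermal_1rdm_satisfies_coleman():
    for spacing in (0.75, 1.5):
        rdm = thermal_rdm(ThermalSpec(hydrogen_chain(3, spacing), p=1))
        assert coleman_check(rdm).coleman_pass
        assert rdm.trace == pytest.approx(3.0, abs=1e-10)


def test_partition_function_consistency():
    """d(log Z)/d(-1/kT) equals the thermal mean energy."""
    ints = hydrogen_chain(2, 1.5)
    basis = build_sector_basis(4, 0, 2, 0)
    E, _ = diagonalize_sector(build_hamiltonian(ints, basis), basis)
    kt = resolve_kt(ThermalSpec(ints), E)
    beta = 1.0 / kt

    def logz(b):
        return float(np.log(np.sum(np.exp(-b * (E - E[0])))) - b * E[0])

    h = 1e-6
    mean_energy = np.sum(E * np.exp(-beta * (E - E[0]))) / np.sum(np.exp(-beta * (E - E[0])))
    assert -(logz(beta + h) - logz(beta - h)) / (2 * h) == pytest.approx(
        mean_energy, abs=1e-6
    )


def test_fcidump_roundtrip(tmp_path):
    ints = hydrogen_chain(3, 0.75)
    path = tmp_path / "h3.fcidump"
    write_fcidump(ints, path)
    loaded = read_fcidump(path)
    assert loaded.K == 3 and loaded.n_electrons == 3
    assert np.abs(loaded.h - ints.h).max() < 1e-14
    assert np.abs(loaded.eri - ints.eri).max() < 1e-14
    assert loaded.core_energy == pytest.approx(ints.core_energy, abs=1e-14)
    # chemist-notation 8-fold symmetry survives the round trip
    e = loaded.eri
    assert np.abs(e - e.transpose(1, 0, 2, 3)).max() < 1e-12
    assert np.abs(e - e.transpose(2, 3, 0, 1)).max() < 1e-12


def test_integral_mismatch_rejected():
    ints = hydrogen_chain(2, 0.75)
    with pytest.raises(ValueError, match="spin-orbitals"):
        build_hamiltonian(ints, build_sector_basis(6, 0, 3, 0))
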