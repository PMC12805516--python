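"""Canonical-ensemble thermal RDM targets for small molecules.

The electronic Hamiltonian ``H = sum h_pq a_p^+ a_q + 1/4 sum <pq||rs>
a_p^+ a_q^+ a_s a_r`` is built over the N-electron determinant sector,
diagonalized densely, and the thermal p-RDM is the Boltzmann-weighted average
``sum_i w_i rho_p(v_i)`` with ``w_i = exp(-E_i / kT) / Z`` over *all* sector
eigenstates (the canonical ensemble constrains the particle number only; no
spin sub-ensemble restriction is applied).

The default temperature rule sets ``kT`` to the gap between the ground level
and the first *distinct* energy above it — for an exactly degenerate ground
multiplet (linear H3's Sz = +-1/2 doublet) the literal first-excited gap
would be zero and the ensemble ill-defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .fock import SectorBasis, StateVector, build_sector_basis, parity_below
from .integrals import MolecularIntegrals
from .rdm import ReducedDensityMatrix, compute_rdm

__all__ = [
    "ThermalSpec",
    "build_hamiltonian",
    "diagonalize_sector",
    "thermal_rdm",
    "reference_occupation",
]

DEGENERACY_TOL = 1e-8


@dataclass
class ThermalSpec:
    """Recipe for a thermal target: integrals + temperature rule + order p."""

    integrals: MolecularIntegrals
    temperature_rule: str = "gap"  # "gap" | "explicit"
    kT: Optional[float] = None  # Hartree, required for the explicit rule
    p: int = 1

    def __post_init__(self):
        if self.temperature_rule not in ("gap", "explicit"):
            raise ValueError(f"unknown temperature rule {self.temperature_rule!r}")
        if self.temperature_rule == "explicit" and (self.kT is None or self.kT <= 0):
            raise ValueError("explicit temperature rule needs kT > 0")


def build_hamiltonian(ints: MolecularIntegrals, basis: SectorBasis) -> np.ndarray:
    """Dense sector Hamiltonian (the sectors used here have dim <= a few hundred)."""
    if basis.M_bath != 0:
        raise ValueError("molecular Hamiltonians act on system-only sectors")
    if basis.M_sys != ints.M:
        raise ValueError(
            f"integral set covers {ints.M} spin-orbitals, basis has {basis.M_sys}"
        )
    h1 = ints.spin_orbital_h()
    v = ints.spin_orbital_v()
    dim = basis.dim
    H = np.zeros((dim, dim))
    M = basis.M_sys
    for col, w in enumerate(basis.states):
        w = int(w)
        occ = [g for g in range(M) if w & (1 << g)]
        # one-body a_p^+ a_q
        for q in occ:
            s1 = parity_below(w, q)
            w1 = w ^ (1 << q)
            for p in range(M):
                if w1 & (1 << p) or abs(h1[p, q]) < 1e-16:
                    continue
                H[basis.index_of[w1 | (1 << p)], col] += (
                    h1[p, q] * s1 * parity_below(w1, p)
                )
        # two-body: sum_{p<q, r<s} <pq||rs> a_p^+ a_q^+ a_s a_r
        for bi in range(len(occ)):
            for bj in range(bi + 1, len(occ)):
                r, s_ = occ[bi], occ[bj]  # r < s; a_r acts first in a_p+ a_q+ a_s a_r
                sgn0 = parity_below(w, r)
                w1 = w ^ (1 << r)
                sgn0 *= parity_below(w1, s_)
                w1 ^= 1 << s_
                for p in range(M):
                    if w1 & (1 << p):
                        continue
                    for q in range(p + 1, M):
                        if w1 & (1 << q):
                            continue
                        val = v[p, q, r, s_]
                        if abs(val) < 1e-16:
                            continue
                        sgn = sgn0 * parity_below(w1, q)
                        w2 = w1 | (1 << q)
                        sgn *= parity_below(w2, p)
                        H[basis.index_of[w2 | (1 << p)], col] += val * sgn
    return H


def diagonalize_sector(H: np.ndarray, basis: SectorBasis) -> Tuple[np.ndarray, np.ndarray]:
    """Ascending eigenenergies and orthonormal eigenvectors of the sector Hamiltonian."""
    if H.shape != (basis.dim, basis.dim):
        raise ValueError("Hamiltonian does not match the basis")
    energies, vectors = np.linalg.eigh(H)
    return energies, vectors


def resolve_kt(spec: ThermalSpec, energies: np.ndarray) -> float:
    if spec.temperature_rule == "explicit":
        return float(spec.kT)
    e0 = energies[0]
    above = energies[energies > e0 + DEGENERACY_TOL]
    if len(above) == 0:
        raise ValueError(
            "all sector energies are degenerate; the gap temperature rule is "
            "undefined — supply an explicit kT"
        )
    return float(above[0] - e0)


def thermal_rdm(spec: ThermalSpec, p: Optional[int] = None) -> ReducedDensityMatrix:
    """Boltzmann-weighted p-RDM of the canonical ensemble."""
    p = spec.p if p is None else p
    ints = spec.integrals
    basis = build_sector_basis(ints.M, 0, ints.n_electrons, 0)
    H = build_hamiltonian(ints, basis)
    energies, vectors = diagonalize_sector(H, basis)
    kt = resolve_kt(spec, energies)
    logw = -(energies - energies[0]) / kt
    w = np.exp(logw)
    w /= w.sum()
    out = None
    for wi, vi in zip(w, vectors.T):
        if wi < 1e-300:
            continue
        mat = compute_rdm(StateVector(basis, vi), p).matrix
        out = wi * mat if out is None else out + wi * mat
    return ReducedDensityMatrix(p, ints.M, ints.n_electrons, out)


def reference_occupation(ints: MolecularIntegrals):
    """Mean-field reference: the N lowest spin-orbitals (alpha first on ties)."""
    from .fock import SpinOrbital

    return [SpinOrbital.from_global_index(g, ints.M) for g in range(ints.n_electrons)]
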