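"""Minimal-basis molecular integrals for hydrogen chains, plus FCIDUMP I/O.

Implements closed-form Gaussian integrals for contracted s-type shells (all a
minimal STO-3G treatment of H_n needs): overlap, kinetic, nuclear attraction
and electron repulsion, following the standard Boys-function expressions.
Orbitals are the canonical eigenvectors of the core Hamiltonian in the
atomic-orbital basis (generalized eigenproblem with the overlap metric); for
H2 these coincide with the restricted Hartree-Fock orbitals by symmetry, and
for linear H3 they are symmetry-adapted, so the lowest-orbital determinant is
the natural mean-field reference in both cases.

Integral containers carry spatial-orbital matrices in chemist notation
``(pq|rs)``; the spin-orbital expansion (physicist antisymmetrized
``<pq||rs>``) used by the second-quantized Hamiltonian is derived on demand
with spin-orbital index ``2*(spatial-1) + spin`` matching the canonical
ordering of :mod:`ensrep.fock`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
from scipy.linalg import eigh
from scipy.special import erf

__all__ = [
    "MolecularIntegrals",
    "sto3g_hydrogen_integrals",
    "hydrogen_chain",
    "write_fcidump",
    "read_fcidump",
]

BOHR_PER_ANGSTROM = 1.8897259886

# STO-3G hydrogen 1s: primitive exponents (zeta = 1.24 scaling folded in) and
# contraction coefficients for unit-normalized primitives.
_STO3G_H_EXP = np.array([3.42525091, 0.62391373, 0.16885540])
_STO3G_H_COEF = np.array([0.15432897, 0.53532814, 0.44463454])


def _boys0(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    out = np.ones_like(t)
    small = t < 1e-12
    ts = np.where(small, 1.0, t)
    out = np.where(small, 1.0 - t / 3.0, 0.5 * np.sqrt(np.pi / ts) * erf(np.sqrt(ts)))
    return out


def _prim_norm(alpha: float) -> float:
    return (2.0 * alpha / np.pi) ** 0.75


@dataclass
class MolecularIntegrals:
    """One- and two-electron integrals over an orthonormal spatial-orbital basis."""

    K: int
    n_electrons: int
    h: np.ndarray  # (K, K) core Hamiltonian, Hartree
    eri: np.ndarray  # (K, K, K, K) chemist (pq|rs), Hartree
    core_energy: float  # nuclear repulsion, Hartree
    orbital_energies: np.ndarray = field(default=None)

    def __post_init__(self):
        self.h = np.asarray(self.h, float)
        self.eri = np.asarray(self.eri, float)
        if self.h.shape != (self.K, self.K):
            raise ValueError("one-electron matrix has the wrong shape")
        if self.eri.shape != (self.K,) * 4:
            raise ValueError("two-electron tensor has the wrong shape")
        if np.abs(self.h - self.h.T).max() > 1e-10:
            raise ValueError("core Hamiltonian must be symmetric")

    @property
    def M(self) -> int:
        return 2 * self.K

    def spin_orbital_h(self) -> np.ndarray:
        """(2K, 2K) one-electron matrix with alpha/beta interleaved."""
        M = self.M
        h1 = np.zeros((M, M))
        for p in range(self.K):
            for q in range(self.K):
                for s in (0, 1):
                    h1[2 * p + s, 2 * q + s] = self.h[p, q]
        return h1

    def spin_orbital_v(self) -> np.ndarray:
        """Antisymmetrized physicist-notation <PQ||RS> over spin-orbitals."""
        M = self.M
        # physicist <pq|rs> = chemist (pr|qs)
        phys = self.eri.transpose(0, 2, 1, 3)
        v = np.zeros((M, M, M, M))
        for s1 in (0, 1):
            for s2 in (0, 1):
                # direct term: sigma(P)=sigma(R), sigma(Q)=sigma(S)
                v[s1::2, s2::2, s1::2, s2::2] += phys
                # exchange term: sigma(P)=sigma(S), sigma(Q)=sigma(R)
                v[s1::2, s2::2, s2::2, s1::2] -= phys.transpose(0, 1, 3, 2)
        return v


def _ao_integrals(centers_bohr: np.ndarray):
    """AO-basis S, T, V, ERI for one contracted s shell per center."""
    n = len(centers_bohr)
    exps, coefs = _STO3G_H_EXP, _STO3G_H_COEF
    norms = np.array([_prim_norm(a) for a in exps])
    c = coefs * norms

    S = np.zeros((n, n))
    T = np.zeros((n, n))
    V = np.zeros((n, n))
    for A in range(n):
        for B in range(n):
            RA, RB = centers_bohr[A], centers_bohr[B]
            rab2 = float(np.dot(RA - RB, RA - RB))
            for a, ca in zip(exps, c):
                for b, cb in zip(exps, c):
                    p = a + b
                    pre = (np.pi / p) ** 1.5 * np.exp(-a * b / p * rab2)
                    S[A, B] += ca * cb * pre
                    T[A, B] += ca * cb * a * b / p * (3.0 - 2.0 * a * b / p * rab2) * pre
                    P = (a * RA + b * RB) / p
                    for Cc in centers_bohr:  # all nuclei have charge 1
                        rpc2 = float(np.dot(P - Cc, P - Cc))
                        V[A, B] -= (
                            ca * cb * 2.0 * np.pi / p
                            * np.exp(-a * b / p * rab2) * float(_boys0(p * rpc2))
                        )

    eri = np.zeros((n, n, n, n))
    for A in range(n):
        for B in range(n):
            RA, RB = centers_bohr[A], centers_bohr[B]
            rab2 = float(np.dot(RA - RB, RA - RB))
            for C in range(n):
                for D in range(n):
                    RC, RD = centers_bohr[C], centers_bohr[D]
                    rcd2 = float(np.dot(RC - RD, RC - RD))
                    val = 0.0
                    for a, ca in zip(exps, c):
                        for b, cb in zip(exps, c):
                            p = a + b
                            P = (a * RA + b * RB) / p
                            eab = np.exp(-a * b / p * rab2)
                            for g, cg in zip(exps, c):
                                for d, cd in zip(exps, c):
                                    q = g + d
                                    Q = (g * RC + d * RD) / q
                                    ecd = np.exp(-g * d / q * rcd2)
                                    rpq2 = float(np.dot(P - Q, P - Q))
                                    val += (
                                        ca * cb * cg * cd
                                        * 2.0 * np.pi**2.5
                                        / (p * q * np.sqrt(p + q))
                                        * eab * ecd
                                        * float(_boys0(p * q / (p + q) * rpq2))
                                    )
                    eri[A, B, C, D] = val
    return S, T, V, eri


def sto3g_hydrogen_integrals(
    coords_angstrom: Sequence[Sequence[float]], n_electrons: int
) -> MolecularIntegrals:
    """Orthonormal-orbital integrals for a cluster of hydrogen atoms."""
    centers = np.asarray(coords_angstrom, float) * BOHR_PER_ANGSTROM
    K = len(centers)
    S, T, V, eri_ao = _ao_integrals(centers)
    hcore = T + V
    # canonical core orbitals: hcore C = S C eps, C^T S C = 1
    eps, C = eigh(hcore, S)
    h_mo = C.T @ hcore @ C
    eri_mo = np.einsum("abcd,ap,bq,cr,ds->pqrs", eri_ao, C, C, C, C, optimize=True)
    e_nuc = 0.0
    for i in range(K):
        for j in range(i + 1, K):
            e_nuc += 1.0 / float(np.linalg.norm(centers[i] - centers[j]))
    return MolecularIntegrals(K, n_electrons, h_mo, eri_mo, e_nuc, eps)


def hydrogen_chain(n_atoms: int, spacing_angstrom: float) -> MolecularIntegrals:
    """Linear H_n with equal adjacent spacing on the z axis."""
    coords = [[0.0, 0.0, i * spacing_angstrom] for i in range(n_atoms)]
    return sto3g_hydrogen_integrals(coords, n_electrons=n_atoms)


# ---------------------------------------------------------------------------
# FCIDUMP (plain-text NAMELIST header + integral records, chemist notation)
# ---------------------------------------------------------------------------


def write_fcidump(ints: MolecularIntegrals, path, ms2: int = None) -> None:
    if ms2 is None:
        ms2 = ints.n_electrons % 2
    K = ints.K
    lines = [
        f"&FCI NORB={K},NELEC={ints.n_electrons},MS2={ms2},",
        "  ORBSYM=" + "1," * K,
        "  ISYM=1,",
        "&END",
    ]

    def rec(val, i, j, k, l):
        lines.append(f"{val: .16E} {i:4d} {j:4d} {k:4d} {l:4d}")

    for p in range(K):
        for q in range(p + 1):
            for r in range(p + 1):
                smax = q if r == p else r
                for s_ in range(smax + 1):
                    val = ints.eri[p, q, r, s_]
                    if abs(val) > 1e-16:
                        rec(val, p + 1, q + 1, r + 1, s_ + 1)
    for p in range(K):
        for q in range(p + 1):
            if abs(ints.h[p, q]) > 1e-16:
                rec(ints.h[p, q], p + 1, q + 1, 0, 0)
    rec(ints.core_energy, 0, 0, 0, 0)
    Path(path).write_text("\n".join(lines) + "\n")


def read_fcidump(path) -> MolecularIntegrals:
    text = Path(path).read_text()
    lines = text.splitlines()
    header = []
    body_start = 0
    for n, line in enumerate(lines):
        header.append(line)
        if "&END" in line.upper() or line.strip() == "/":
            body_start = n + 1
            break
    head = " ".join(header).upper().replace("&FCI", " ").replace("&END", " ")
    fields = {}
    for chunk in head.replace("\n", " ").split(","):
        if "=" in chunk:
            key, _, val = chunk.partition("=")
            vals = val.strip().rstrip(",").split()
            if vals:
                fields[key.strip()] = vals[0]
    K = int(fields["NORB"])
    nelec = int(fields["NELEC"])
    h = np.zeros((K, K))
    eri = np.zeros((K, K, K, K))
    e_core = 0.0
    for line in lines[body_start:]:
        toks = line.split()
        if len(toks) != 5:
            continue
        val = float(toks[0].replace("D", "E").replace("d", "e"))
        i, j, k, l = (int(t) for t in toks[1:])
        if i == 0:
            e_core = val
        elif k == 0:
            h[i - 1, j - 1] = h[j - 1, i - 1] = val
        else:
            p, q, r, s_ = i - 1, j - 1, k - 1, l - 1
            for a, b in ((p, q), (q, p)):
                for c, d in ((r, s_), (s_, r)):
                    eri[a, b, c, d] = eri[c, d, a, b] = val
    return MolecularIntegrals(K, nelec, h, eri, e_core)
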