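"""Occupation-number-basis representation of fermionic states.

States live in a fixed particle-number sector of a Fock space built over a
*system* register of spin-orbitals, optionally extended by a *bath* register
used for purifications of ensemble states.  All fermionic phases are computed
directly on occupation bitstrings (parity of the set bits between two sites),
which for the canonical ordering chosen here is exactly the Jordan-Wigner sign
convention; no qubit-operator expansion is ever constructed.

Canonical spin-orbital ordering
-------------------------------
System register first, then bath.  Within a register, spatial orbitals in
ascending order; within a spatial orbital, alpha before beta.  The global
index of a spin-orbital is its position in this ordering, and bit ``g`` of an
occupation word refers to global index ``g``.  Basis determinants within a
sector are ordered by ascending integer value of the occupation word.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Dict, List, Sequence, Tuple

import numpy as np

__all__ = [
    "SpinOrbital",
    "SectorBasis",
    "StateVector",
    "build_sector_basis",
    "slater_determinant",
    "apply_excitation",
    "apply_exponential",
    "annihilation_map",
    "pair_annihilation_map",
]

ALPHA = "alpha"
BETA = "beta"
SYSTEM = "system"
BATH = "bath"

_SPIN_OFFSET = {ALPHA: 0, BETA: 1}


@dataclass(frozen=True, order=True)
class SpinOrbital:
    """One spin-orbital, identified by register, 1-based spatial index, spin."""

    register: str
    spatial_index: int
    spin: str

    def __post_init__(self):
        if self.register not in (SYSTEM, BATH):
            raise ValueError(f"unknown register {self.register!r}")
        if self.spatial_index < 1:
            raise ValueError("spatial_index is 1-based and must be >= 1")
        if self.spin not in (ALPHA, BETA):
            raise ValueError(f"unknown spin {self.spin!r}")

    def global_index(self, m_sys: int) -> int:
        """Position in the canonical ordering given ``m_sys`` system spin-orbitals."""
        offset = 0 if self.register == SYSTEM else m_sys
        return offset + 2 * (self.spatial_index - 1) + _SPIN_OFFSET[self.spin]

    @staticmethod
    def from_global_index(g: int, m_sys: int) -> "SpinOrbital":
        register = SYSTEM if g < m_sys else BATH
        local = g if g < m_sys else g - m_sys
        return SpinOrbital(register, local // 2 + 1, ALPHA if local % 2 == 0 else BETA)


def so(spatial_index: int, spin: str, register: str = SYSTEM) -> SpinOrbital:
    """Shorthand constructor used throughout tests and scenario configs."""
    return SpinOrbital(register, spatial_index, spin)


@dataclass
class SectorBasis:
    """All determinants with fixed electron counts on each register."""

    M_sys: int
    M_bath: int
    N_sys: int
    N_bath: int
    states: np.ndarray = field(repr=False)  # int64 occupation words, ascending
    index_of: Dict[int, int] = field(repr=False)

    @property
    def M(self) -> int:
        return self.M_sys + self.M_bath

    @property
    def dim(self) -> int:
        return len(self.states)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SectorBasis)
            and (self.M_sys, self.M_bath, self.N_sys, self.N_bath)
            == (other.M_sys, other.M_bath, other.N_sys, other.N_bath)
        )

    def __hash__(self) -> int:
        return hash((self.M_sys, self.M_bath, self.N_sys, self.N_bath))


def build_sector_basis(M_sys: int, M_bath: int, N_sys: int, N_bath: int) -> SectorBasis:
    """Enumerate the determinant basis of a fixed (N_sys, N_bath) sector.

    The basis has ``C(M_sys, N_sys) * C(M_bath, N_bath)`` determinants, ordered
    by ascending integer value of the occupation word.
    """
    if not 0 <= N_sys <= M_sys:
        raise ValueError(f"system register: need 0 <= N_sys={N_sys} <= M_sys={M_sys}")
    if not 0 <= N_bath <= M_bath:
        raise ValueError(f"bath register: need 0 <= N_bath={N_bath} <= M_bath={M_bath}")
    sys_words = [
        sum(1 << b for b in occ) for occ in combinations(range(M_sys), N_sys)
    ]
    bath_words = [
        sum(1 << (M_sys + b) for b in occ)
        for occ in combinations(range(M_bath), N_bath)
    ]
    words = sorted(s | b for s in sys_words for b in bath_words)
    assert len(words) == comb(M_sys, N_sys) * comb(M_bath, N_bath)
    states = np.asarray(words, dtype=np.int64)
    return SectorBasis(
        M_sys, M_bath, N_sys, N_bath, states, {w: i for i, w in enumerate(words)}
    )


@dataclass
class StateVector:
    """Complex amplitudes over the determinants of a :class:`SectorBasis`."""

    basis: SectorBasis
    amplitudes: np.ndarray

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.complex128)
        if self.amplitudes.shape != (self.basis.dim,):
            raise ValueError("amplitude vector length does not match basis size")

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.amplitudes))

    def normalized(self) -> "StateVector":
        n = self.norm
        if n == 0.0:
            raise ValueError("cannot normalize the zero vector")
        return StateVector(self.basis, self.amplitudes / n)

    def overlap(self, other: "StateVector") -> complex:
        if self.basis != other.basis:
            raise ValueError("states live in different sectors")
        return complex(np.vdot(self.amplitudes, other.amplitudes))


def _register_counts(word: int, m_sys: int, m_tot: int) -> Tuple[int, int]:
    sys_mask = (1 << m_sys) - 1
    n_sys = bin(word & sys_mask).count("1")
    return n_sys, bin(word).count("1") - n_sys


def occupation_word(occupied: Sequence[SpinOrbital], m_sys: int) -> int:
    """Occupation word of a determinant; rejects Pauli-violating repeats."""
    word = 0
    for orb in occupied:
        bit = 1 << orb.global_index(m_sys)
        if word & bit:
            raise ValueError(f"spin-orbital {orb} listed twice (Pauli exclusion)")
        word |= bit
    return word


def slater_determinant(basis: SectorBasis, occupied: Sequence[SpinOrbital]) -> StateVector:
    """Unit vector on a single determinant of the sector.

    The determinant is the ordered product of creation operators in canonical
    order acting on the vacuum, so its amplitude is +1 by convention.
    """
    word = occupation_word(occupied, basis.M_sys)
    n_sys, n_bath = _register_counts(word, basis.M_sys, basis.M)
    if n_sys != basis.N_sys or n_bath != basis.N_bath:
        raise ValueError(
            f"determinant occupies ({n_sys},{n_bath}) electrons but the sector "
            f"requires ({basis.N_sys},{basis.N_bath})"
        )
    amp = np.zeros(basis.dim, dtype=np.complex128)
    amp[basis.index_of[word]] = 1.0
    return StateVector(basis, amp)


def parity_below(word: int, g: int) -> int:
    """(-1)^(number of occupied spin-orbitals with global index < g)."""
    return -1 if bin(word & ((1 << g) - 1)).count("1") & 1 else 1


# ---------------------------------------------------------------------------
# Cached linear maps between adjacent sectors (used for RDMs and gradients).
# ---------------------------------------------------------------------------

_ANNIHILATION_CACHE: Dict[Tuple, Tuple] = {}


def lowered_basis(basis: SectorBasis, k: int) -> SectorBasis:
    """Sector reached from ``basis`` by annihilating one electron at global index k."""
    if k < basis.M_sys:
        return build_sector_basis(basis.M_sys, basis.M_bath, basis.N_sys - 1, basis.N_bath)
    return build_sector_basis(basis.M_sys, basis.M_bath, basis.N_sys, basis.N_bath - 1)


def annihilation_map(basis: SectorBasis, k: int):
    """Index/sign arrays realizing a_k : sector -> lowered sector.

    Returns ``(target_basis, src_idx, dst_idx, signs)`` such that
    ``out[dst_idx] = signs * psi[src_idx]`` is ``a_k |psi>``.
    """
    key = (basis.M_sys, basis.M_bath, basis.N_sys, basis.N_bath, k)
    if key in _ANNIHILATION_CACHE:
        return _ANNIHILATION_CACHE[key]
    target = lowered_basis(basis, k)
    src, dst, sgn = [], [], []
    bit = 1 << k
    for i, w in enumerate(basis.states):
        w = int(w)
        if w & bit:
            src.append(i)
            dst.append(target.index_of[w ^ bit])
            sgn.append(parity_below(w, k))
    out = (
        target,
        np.asarray(src, dtype=np.int64),
        np.asarray(dst, dtype=np.int64),
        np.asarray(sgn, dtype=np.float64),
    )
    _ANNIHILATION_CACHE[key] = out
    return out


def apply_annihilation(psi: StateVector, k: int) -> StateVector:
    target, src, dst, sgn = annihilation_map(psi.basis, k)
    out = np.zeros(target.dim, dtype=np.complex128)
    out[dst] = sgn * psi.amplitudes[src]
    return StateVector(target, out)


# ---------------------------------------------------------------------------
# Action of antihermitian excitation-deexcitation generators.
#
# A pool generator O = E - E^T, where E is the (de)excitation part, is a real
# antisymmetric matrix whose nonzero pattern is a signed partial permutation:
# each determinant is coupled to at most one other determinant, and no
# determinant is simultaneously a source and a target (the construction in
# :mod:`ensrep.pool` asserts this).  Hence O decomposes into independent 2x2
# rotation blocks, O^3 = -O, and the exponential is exact:
#
#     exp(theta O) = 1 + sin(theta) O + (1 - cos(theta)) O^2.
# ---------------------------------------------------------------------------


def apply_excitation(op, psi: StateVector) -> StateVector:
    """Apply an antihermitian pool generator O = E - E^T to a state (not normalized)."""
    if op.basis != psi.basis:
        raise ValueError("operator was built for a different sector")
    out = np.zeros(psi.basis.dim, dtype=np.complex128)
    np.add.at(out, op.rows, op.signs * psi.amplitudes[op.cols])
    np.add.at(out, op.cols, -op.signs * psi.amplitudes[op.rows])
    return StateVector(psi.basis, out)


def _generator_apply(op, vec: np.ndarray) -> np.ndarray:
    out = np.zeros_like(vec)
    out[op.rows] += op.signs * vec[op.cols]
    out[op.cols] -= op.signs * vec[op.rows]
    return out


def apply_exponential(op, theta: float, psi: StateVector) -> StateVector:
    """Apply exp(theta*O) exactly (closed form, no Trotterization)."""
    if not np.isfinite(theta):
        raise ValueError("rotation angle must be finite")
    if op.basis != psi.basis:
        raise ValueError("operator was built for a different sector")
    amp = exp_apply_amplitudes(op, float(theta), psi.amplitudes)
    return StateVector(psi.basis, amp)


def exp_apply_amplitudes(op, theta: float, amp: np.ndarray) -> np.ndarray:
    """Raw-array version of :func:`apply_exponential` (hot path of the optimizer)."""
    u = _generator_apply(op, amp)
    w = _generator_apply(op, u)
    return amp + np.sin(theta) * u + (1.0 - np.cos(theta)) * w


def pair_annihilation_map(basis: SectorBasis, k: int, l: int):
    """Index/sign arrays realizing a_l a_k : sector -> doubly lowered sector."""
    key = (basis.M_sys, basis.M_bath, basis.N_sys, basis.N_bath, k, l, "pair")
    if key in _ANNIHILATION_CACHE:
        return _ANNIHILATION_CACHE[key]
    if k == l:
        raise ValueError("pair annihilation requires distinct indices")
    mid, src1, dst1, sgn1 = annihilation_map(basis, k)
    target, src2, dst2, sgn2 = annihilation_map(mid, l)
    # compose the two one-electron maps
    lookup = -np.ones(mid.dim, dtype=np.int64)
    lookup[src2] = np.arange(len(src2))
    pos = lookup[dst1]
    keep = pos >= 0
    src = src1[keep]
    dst = dst2[pos[keep]]
    sgn = sgn1[keep] * sgn2[pos[keep]]
    out = (target, src, dst, sgn)
    _ANNIHILATION_CACHE[key] = out
    return out
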