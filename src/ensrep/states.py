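"""Target and initial states: determinant mixtures and purifications.

Targets are built as convex mixtures ``rho = sum_i w_i |phi_i><phi_i|`` of
Slater determinants, reduced to a p-RDM.  An ensemble search starts from the
product purification ``|phi_0> (x) |phi_0>`` with the bath register mirroring
the system register; the adaptive loop has to discover the entangled
purification of a genuine mixture on its own.  For consistency tests an
explicit purification of a K-component mixture is also provided, pairing the
i-th component with the i-th member of a fixed orthonormal family of bath
determinants (orthonormal tags).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .fock import (
    SectorBasis,
    SpinOrbital,
    StateVector,
    build_sector_basis,
    occupation_word,
    slater_determinant,
)
from .rdm import ReducedDensityMatrix, add_noise, compute_rdm

__all__ = [
    "MixtureSpec",
    "TargetSpec",
    "mixture_target",
    "purify_product",
    "purify_mixture",
    "initial_state",
    "build_target",
]


@dataclass
class MixtureSpec:
    """Convex combination of Slater determinants with weights summing to 1."""

    components: List[Tuple[List[SpinOrbital], float]]

    def __post_init__(self):
        if not self.components:
            raise ValueError("a mixture needs at least one component")
        weights = np.array([w for _, w in self.components], dtype=float)
        if np.any(weights < 0):
            raise ValueError("mixture weights must be non-negative")
        if abs(weights.sum() - 1.0) > 1e-12:
            raise ValueError(f"mixture weights sum to {weights.sum()}, not 1")
        counts = {len(occ) for occ, _ in self.components}
        if len(counts) != 1:
            raise ValueError("all mixture components must share one electron count")

    @property
    def n_electrons(self) -> int:
        return len(self.components[0][0])

    @staticmethod
    def two_state(rho1: Sequence[SpinOrbital], rho2: Sequence[SpinOrbital], w: float) -> "MixtureSpec":
        """Two-component mixture with ``w = 0`` reducing to the reference rho_1.

        The mixing convention is ``(1 - w) rho_1 + w rho_2``: the w = 0 end of
        the family is the reference determinant itself (whose own reduced
        matrix is trivially pure-representable) and w = 0.5 is the symmetric
        ensemble.
        """
        if not 0.0 <= w <= 1.0:
            raise ValueError("mixing weight must lie in [0, 1]")
        return MixtureSpec([(list(rho1), 1.0 - w), (list(rho2), w)])


@dataclass
class TargetSpec:
    """Declarative recipe for a target p-RDM (mixture, thermal or file)."""

    kind: str  # "mixture" | "thermal" | "file"
    p: int
    M_sys: int = 0
    mixture: Optional[MixtureSpec] = None
    thermal: Optional[object] = None  # ensrep.thermal.ThermalSpec
    path: Optional[str] = None
    noise_eps: float = 0.0
    noise_seed: int = 0
    hermitize_noise: bool = True

    def __post_init__(self):
        payloads = {"mixture": self.mixture, "thermal": self.thermal, "file": self.path}
        if self.kind not in payloads:
            raise ValueError(f"unknown target kind {self.kind!r}")
        if payloads[self.kind] is None:
            raise ValueError(f"target kind {self.kind!r} needs its payload")
        if sum(v is not None for v in payloads.values()) != 1:
            raise ValueError("exactly one target payload may be present")
        if self.p not in (1, 2):
            raise ValueError("p must be 1 or 2")
        if self.noise_eps < 0:
            raise ValueError("noise strength must be non-negative")


def mixture_target(spec: MixtureSpec, p: int, M_sys: int) -> ReducedDensityMatrix:
    """p-RDM of a determinant mixture, normalized to trace p! C(N, p)."""
    N = spec.n_electrons
    basis = build_sector_basis(M_sys, 0, N, 0)
    out = None
    for occ, w in spec.components:
        rdm = compute_rdm(slater_determinant(basis, occ), p)
        out = w * rdm.matrix if out is None else out + w * rdm.matrix
    return ReducedDensityMatrix(p, M_sys, N, out)


def purify_product(phi0: StateVector) -> StateVector:
    """Product purification |phi_0> (x) |phi_0| on the doubled register.

    The bath register mirrors the system register one-to-one; because every
    system spin-orbital precedes every bath spin-orbital in the canonical
    ordering, the combined determinants pick up no reordering signs.
    """
    basis = phi0.basis
    if basis.M_bath != 0:
        raise ValueError("the reference state must live on a system-only sector")
    if abs(phi0.norm - 1.0) > 1e-10:
        raise ValueError("the reference state must be normalized")
    M, N = basis.M_sys, basis.N_sys
    ext = build_sector_basis(M, M, N, N)
    amp = np.zeros(ext.dim, dtype=np.complex128)
    nz = np.nonzero(phi0.amplitudes)[0]
    for a in nz:
        wa = int(basis.states[a])
        for b in nz:
            wb = int(basis.states[b])
            amp[ext.index_of[wa | (wb << M)]] = phi0.amplitudes[a] * phi0.amplitudes[b]
    return StateVector(ext, amp)


def _bath_tag_words(M: int, N: int, count: int) -> List[int]:
    """First ``count`` bath determinants in lexicographic order (orthonormal tags)."""
    from itertools import combinations

    tags = []
    for occ in combinations(range(M), N):
        tags.append(sum(1 << (M + b) for b in occ))
        if len(tags) == count:
            return tags
    raise ValueError(f"bath register supports only {len(tags)} orthogonal tags")


def purify_mixture(spec: MixtureSpec, M_sys: int) -> StateVector:
    """Explicit purification sum_i sqrt(w_i) |phi_i> (x) |b_i> of a mixture."""
    N = spec.n_electrons
    ext = build_sector_basis(M_sys, M_sys, N, N)
    tags = _bath_tag_words(M_sys, N, len(spec.components))
    amp = np.zeros(ext.dim, dtype=np.complex128)
    for (occ, w), tag in zip(spec.components, tags):
        word = occupation_word(occ, M_sys) | tag
        amp[ext.index_of[word]] += np.sqrt(w)
    return StateVector(ext, amp).normalized()


def initial_state(scenario: str, reference, M_sys: int) -> StateVector:
    """Initial state of a run: the reference determinant, or its product purification.

    ``reference`` is either a list of occupied system :class:`SpinOrbital`
    or a :class:`MixtureSpec`, in which case its first component (rho_1) is
    the reference determinant.
    """
    if isinstance(reference, MixtureSpec):
        occupied = reference.components[0][0]
    else:
        occupied = list(reference)
    N = len(occupied)
    basis = build_sector_basis(M_sys, 0, N, 0)
    phi0 = slater_determinant(basis, occupied)
    if scenario == "pure":
        return phi0
    if scenario == "ensemble":
        return purify_product(phi0)
    raise ValueError(f"unknown scenario {scenario!r}")


def build_target(spec: TargetSpec) -> ReducedDensityMatrix:
    """Materialize a TargetSpec into a concrete (optionally noisy) p-RDM."""
    if spec.kind == "mixture":
        if spec.M_sys <= 0:
            raise ValueError("mixture targets need M_sys")
        rdm = mixture_target(spec.mixture, spec.p, spec.M_sys)
    elif spec.kind == "thermal":
        from .thermal import thermal_rdm

        rdm = thermal_rdm(spec.thermal, p=spec.p)
    else:
        rdm = ReducedDensityMatrix.load(spec.path)
        if rdm.p != spec.p:
            raise ValueError("file target has a different p than requested")
    if spec.noise_eps > 0:
        rdm = add_noise(rdm, spec.noise_eps, spec.noise_seed, spec.hermitize_noise)
    return rdm
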