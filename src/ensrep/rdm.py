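"""Reduced density matrices: construction, distances, audits, noise, I/O.

The p-body reduced density matrix of an N-electron (possibly purified) state
is taken with the quantum-chemistry normalization ``tr(rho_p) = p! C(N, p)``
(N for p = 1, N(N-1) for p = 2).  Elements refer to *system* spin-orbitals
only; when the state lives on an extended system+bath space, the bath is
traced out implicitly because the transition operators act on system orbitals
alone.

Conventions
-----------
* 1-RDM: ``rho[i, k] = <a_i^+ a_k>``, an M x M Hermitian matrix.
* 2-RDM: ``rho[(i,j), (k,l)] = <a_i^+ a_j^+ a_l a_k>`` over *ordered* pairs,
  stored as an M^2 x M^2 matrix with composite row index ``i*M + j``.  The
  fermionic antisymmetry is explicit (rows/columns with i = j vanish), so
  every physical element appears four times; squared distances consistently
  count this multiplicity for both operands.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .fock import StateVector, annihilation_map, pair_annihilation_map

__all__ = [
    "ReducedDensityMatrix",
    "AuditReport",
    "InequalitySet",
    "compute_rdm",
    "hs_distance_sq",
    "contract_2rdm",
    "coleman_check",
    "klyachko_check",
    "add_noise",
    "load_inequalities",
    "bundled_inequalities",
]


@dataclass
class ReducedDensityMatrix:
    """A Hermitian p-body matrix over system spin-orbitals."""

    p: int
    M_sys: int
    N: int
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.complex128)
        d = self.M_sys if self.p == 1 else self.M_sys**2
        if self.p not in (1, 2):
            raise ValueError("only p = 1 and p = 2 reduced matrices are supported")
        if self.matrix.shape != (d, d):
            raise ValueError(f"expected a {d} x {d} matrix for p = {self.p}")

    @property
    def trace(self) -> float:
        return float(np.trace(self.matrix).real)

    @property
    def expected_trace(self) -> float:
        from math import factorial

        return factorial(self.p) * comb(self.N, self.p)

    def eigenvalues(self) -> np.ndarray:
        """Descending eigenvalues of the Hermitian part."""
        h = 0.5 * (self.matrix + self.matrix.conj().T)
        return np.linalg.eigvalsh(h)[::-1]

    def copy(self) -> "ReducedDensityMatrix":
        return ReducedDensityMatrix(self.p, self.M_sys, self.N, self.matrix.copy())

    # -- plain-text / binary round-trip ------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        if path.suffix == ".npy":
            np.save(path, self.matrix, allow_pickle=False)
            meta = path.with_suffix(".meta")
            meta.write_text(f"p {self.p}\nM_sys {self.M_sys}\nN {self.N}\n")
            return
        with open(path, "w") as fh:
            fh.write(f"# ensrep rdm\np {self.p}\nM_sys {self.M_sys}\nN {self.N}\n")
            for row in self.matrix:
                fh.write(" ".join(f"{v.real:+.17e}{v.imag:+.17e}j" for v in row) + "\n")

    @staticmethod
    def load(path) -> "ReducedDensityMatrix":
        path = Path(path)
        if path.suffix == ".npy":
            meta = dict(
                line.split() for line in path.with_suffix(".meta").read_text().splitlines()
            )
            return ReducedDensityMatrix(
                int(meta["p"]), int(meta["M_sys"]), int(meta["N"]),
                np.load(path, allow_pickle=False),
            )
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        meta = dict(l.split() for l in lines[:3])
        rows = [np.array([complex(tok) for tok in l.split()]) for l in lines[3:]]
        return ReducedDensityMatrix(
            int(meta["p"]), int(meta["M_sys"]), int(meta["N"]), np.array(rows)
        )


def pair_index(i: int, j: int, M: int) -> int:
    return i * M + j


def _ordered_pairs(M: int) -> List[Tuple[int, int]]:
    return [(k, l) for k in range(M) for l in range(M) if k != l]


def _pair_vectors(psi: StateVector) -> Tuple[np.ndarray, List[Tuple[int, int]]]:
    """Columns ``a_l a_k |psi>`` for all ordered system pairs (k, l)."""
    basis = psi.basis
    M = basis.M_sys
    pairs = _ordered_pairs(M)
    first = None
    cols = {}
    for k, l in pairs:
        if k < l:
            target, src, dst, sgn = pair_annihilation_map(basis, k, l)
            if first is None:
                first = target
            v = np.zeros(target.dim, dtype=np.complex128)
            v[dst] = sgn * psi.amplitudes[src]
            cols[(k, l)] = v
            cols[(l, k)] = -v
    W = np.column_stack([cols[p] for p in pairs]) if pairs else np.zeros((0, 0))
    return W, pairs


def _single_vectors(psi: StateVector) -> np.ndarray:
    basis = psi.basis
    M = basis.M_sys
    target0 = None
    vecs = []
    for k in range(M):
        target, src, dst, sgn = annihilation_map(basis, k)
        if target0 is None:
            target0 = target
        v = np.zeros(target.dim, dtype=np.complex128)
        v[dst] = sgn * psi.amplitudes[src]
        vecs.append(v)
    return np.column_stack(vecs)


def compute_rdm(psi: StateVector, p: int) -> ReducedDensityMatrix:
    """p-RDM of a normalized state, bath degrees of freedom traced out."""
    if p not in (1, 2):
        raise ValueError("unsupported reduced-matrix order; p must be 1 or 2")
    basis = psi.basis
    M = basis.M_sys
    if p == 1:
        V = _single_vectors(psi)
        mat = V.conj().T @ V  # rho[i,k] = <a_i psi | a_k psi>
        return ReducedDensityMatrix(1, M, basis.N_sys, mat)
    W, pairs = _pair_vectors(psi)
    G = W.conj().T @ W  # rho[(i,j),(k,l)] = <a_j a_i psi | a_l a_k psi>
    mat = np.zeros((M * M, M * M), dtype=np.complex128)
    idx = np.array([pair_index(k, l, M) for k, l in pairs])
    mat[np.ix_(idx, idx)] = G
    return ReducedDensityMatrix(2, M, basis.N_sys, mat)


def hs_distance_sq(a: ReducedDensityMatrix, b: ReducedDensityMatrix) -> float:
    """Squared Hilbert-Schmidt (Frobenius) distance between two p-RDMs."""
    if a.p != b.p or a.M_sys != b.M_sys:
        raise ValueError("matrices must share p and spin-orbital count")
    return float(np.sum(np.abs(a.matrix - b.matrix) ** 2))


def contract_2rdm(rdm2: ReducedDensityMatrix) -> ReducedDensityMatrix:
    """Partial trace of a 2-RDM down to the 1-RDM (trace N)."""
    if rdm2.p != 2:
        raise ValueError("contraction requires a 2-RDM")
    if rdm2.N <= 1:
        raise ValueError("contraction undefined for N <= 1")
    M = rdm2.M_sys
    G = rdm2.matrix.reshape(M, M, M, M)  # [(i,j),(k,l)] -> [i,j,k,l]
    gamma = np.einsum("ijkj->ik", G) / (rdm2.N - 1)
    return ReducedDensityMatrix(1, M, rdm2.N, gamma)


# ---------------------------------------------------------------------------
# Audits: Coleman ensemble conditions, Klyachko generalized Pauli conditions.
# ---------------------------------------------------------------------------


@dataclass
class AuditReport:
    coleman_pass: bool
    eigenvalues: np.ndarray
    trace: float
    klyachko_satisfied: int = 0
    klyachko_total: int = 0
    violations: List[Tuple[str, float]] = field(default_factory=list)


def coleman_check(rdm1: ReducedDensityMatrix, tol: float = 1e-8) -> AuditReport:
    """Ensemble N-representability of a 1-RDM: eigenvalues in [0, 1], trace N."""
    if rdm1.p != 1:
        raise ValueError("Coleman conditions apply to 1-RDMs")
    ev = rdm1.eigenvalues()
    violations = []
    for n, lam in enumerate(ev, start=1):
        if lam < -tol or lam > 1.0 + tol:
            violations.append((f"0 <= lambda_{n} <= 1", float(min(lam, 1.0 - lam))))
    tr = rdm1.trace
    if abs(tr - rdm1.N) > tol:
        violations.append((f"trace == {rdm1.N}", float(-(abs(tr - rdm1.N)))))
    return AuditReport(coleman_pass=not violations, eigenvalues=ev, trace=tr,
                       violations=violations)


@dataclass
class InequalitySet:
    """Affine inequalities on descending 1-RDM eigenvalues: coeff . lambda <= const."""

    N: int
    M: int
    coeffs: np.ndarray  # (n_ineq, M)
    consts: np.ndarray  # (n_ineq,)
    labels: List[str]

    def __len__(self) -> int:
        return len(self.consts)


def load_inequalities(path) -> InequalitySet:
    """Read an inequality set from its plain-text format.

    Header line: ``N M``.  Each record: M integer coefficients, the token
    ``<=`` and a constant; everything after ``#`` is comment.
    """
    rows, consts, labels = [], [], []
    header = None
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if header is None:
            header = tuple(int(t) for t in line.split())
            continue
        toks = line.split()
        assert toks[-2] == "<=", f"malformed inequality record: {raw!r}"
        rows.append([float(t) for t in toks[:-2]])
        consts.append(float(toks[-1]))
        labels.append(" ".join(toks))
    if header is None or not rows:
        raise ValueError(f"no inequalities found in {path}")
    N, M = header
    return InequalitySet(N, M, np.array(rows), np.array(consts), labels)


def bundled_inequalities(N: int, M: int) -> InequalitySet:
    """Load the inequality set shipped with the package for (N, M)."""
    name = f"klyachko_{N}_{M}.txt"
    ref = importlib.resources.files("ensrep.data").joinpath(name)
    with importlib.resources.as_file(ref) as path:
        return load_inequalities(path)


def klyachko_check(
    rdm1: ReducedDensityMatrix,
    ineqs: InequalitySet,
    tol: float = 1e-8,
) -> AuditReport:
    """Count satisfied generalized Pauli (pure-state) constraints.

    The RDM may have fewer spin-orbitals than the inequality set; its
    descending spectrum is then padded with zeros (a state on M' < M orbitals
    is also a state on M orbitals with the extra orbitals empty).
    """
    if rdm1.p != 1:
        raise ValueError("Klyachko conditions apply to 1-RDMs")
    if rdm1.N != ineqs.N:
        raise ValueError(f"inequality set is for N = {ineqs.N}, matrix has N = {rdm1.N}")
    if rdm1.M_sys > ineqs.M:
        raise ValueError(f"inequality set covers only M = {ineqs.M} spin-orbitals")
    lam = np.zeros(ineqs.M)
    lam[: rdm1.M_sys] = rdm1.eigenvalues()
    margins = ineqs.consts - ineqs.coeffs @ lam
    satisfied = margins >= -tol
    violations = [
        (ineqs.labels[i], float(margins[i])) for i in np.nonzero(~satisfied)[0]
    ]
    coleman = coleman_check(rdm1, tol)
    return AuditReport(
        coleman_pass=coleman.coleman_pass,
        eigenvalues=coleman.eigenvalues,
        trace=coleman.trace,
        klyachko_satisfied=int(satisfied.sum()),
        klyachko_total=len(ineqs),
        violations=violations,
    )


def add_noise(
    rdm: ReducedDensityMatrix,
    eps: float,
    seed: int,
    hermitize: bool = True,
) -> ReducedDensityMatrix:
    """Perturb a target with elementwise uniform[-1, 1] noise of strength eps.

    By default the noise matrix is Hermitized (R <- (R + R^+)/2) so that the
    perturbed target remains a valid Hermitian matrix; ``hermitize=False``
    keeps the raw draw, in which case the antihermitian part contributes an
    irreducible floor to any distance minimization.
    """
    if eps < 0:
        raise ValueError("noise strength must be non-negative")
    if eps == 0:
        return rdm.copy()
    rng = np.random.default_rng(seed)
    R = rng.uniform(-1.0, 1.0, size=rdm.matrix.shape)
    if hermitize:
        R = 0.5 * (R + R.T)
    return ReducedDensityMatrix(rdm.p, rdm.M_sys, rdm.N, rdm.matrix + eps * R)


# ---------------------------------------------------------------------------
# Cost function machinery shared by operator selection and re-optimization.
# ---------------------------------------------------------------------------


def distance_to_target(psi: StateVector, target: ReducedDensityMatrix) -> float:
    """Squared Hilbert-Schmidt distance of the state's p-RDM to the target."""
    return hs_distance_sq(compute_rdm(psi, target.p), target)


def distance_state_gradient(
    psi: StateVector, target: ReducedDensityMatrix
) -> Tuple[float, np.ndarray]:
    """Squared distance D(psi) and its Wirtinger gradient dD/d(psi*).

    With Delta = rho_p(psi) - target, the gradient state is
    ``g = 2 sum_ab Delta_ba Gamma_ab |psi>`` where Gamma_ab are the p-body
    transition operators; D then varies as ``dD = 2 Re <g | d psi>``.
    """
    basis = psi.basis
    M = basis.M_sys
    if target.M_sys != M:
        raise ValueError("target does not match the system register size")
    g = np.zeros(basis.dim, dtype=np.complex128)
    if target.p == 1:
        V = _single_vectors(psi)
        rho = V.conj().T @ V
        delta = rho - target.matrix
        D = float(np.sum(np.abs(delta) ** 2))
        U = V @ delta  # column a: sum_b Delta[b, a] * v_b
        for a in range(M):
            _, src, dst, sgn = annihilation_map(basis, a)
            g[src] += sgn * U[dst, a]
        return D, 2.0 * g
    # p == 2
    W, pairs = _pair_vectors(psi)
    G = W.conj().T @ W
    idx = np.array([pair_index(k, l, M) for k, l in pairs])
    rho = np.zeros((M * M, M * M), dtype=np.complex128)
    rho[np.ix_(idx, idx)] = G
    delta_full = rho - target.matrix
    D = float(np.sum(np.abs(delta_full) ** 2))
    delta = delta_full[np.ix_(idx, idx)]
    U = W @ delta
    for a, (i, j) in enumerate(pairs):
        if i < j:
            _, src, dst, sgn = pair_annihilation_map(basis, i, j)
            # column for (i,j) plus the antisymmetric partner (j,i)
            col = U[:, a] - U[:, pairs.index((j, i))]
            g[src] += sgn * col[dst]
    return D, 2.0 * g
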