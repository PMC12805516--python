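"""Restricted antihermitian excitation-deexcitation operator pools.

The pool contains one-body generators ``O_ik = a_i^+ a_k - a_k^+ a_i`` and
two-body generators ``O_ijkl = a_i^+ a_j^+ a_k a_l - a_k^+ a_l^+ a_i a_j``.
For ensemble (purified) runs the pool is restricted so that no generator
changes the electron count of the system register or of the bath register;
this keeps the search inside the canonical-ensemble sector.  Spin (Sz)
conservation is optionally imposed on top of that.

Generators are stored as index/sign arrays of their excitation part ``E``
(``O = E - E^T``, real) on a fixed working sector, which makes both the
generator action and its exact exponential cheap (see :mod:`ensrep.fock`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .fock import SectorBasis, StateVector, parity_below

__all__ = ["PoolOperator", "PoolConfig", "build_pool", "pool_gradients", "dump_pool"]


@dataclass
class PoolOperator:
    """Antihermitian generator restricted to one particle-number sector."""

    kind: str  # "single" | "double"
    indices: Tuple[int, ...]  # (i, k) or (i, j, k, l), global spin-orbital indices
    basis: SectorBasis
    rows: np.ndarray = field(repr=False)  # targets of the excitation part
    cols: np.ndarray = field(repr=False)  # sources of the excitation part
    signs: np.ndarray = field(repr=False)

    @property
    def label(self) -> str:
        if self.kind == "single":
            i, k = self.indices
            return f"O({i}<-{k})"
        i, j, k, l = self.indices
        return f"O({i},{j}<-{k},{l})"

    def dense(self) -> np.ndarray:
        """Dense matrix of the generator (tests / small sectors only)."""
        d = self.basis.dim
        m = np.zeros((d, d))
        m[self.rows, self.cols] = self.signs
        return m - m.T


@dataclass
class PoolConfig:
    """Switches that fully determine pool membership and ordering."""

    conserve_register_number: bool = True
    # Spin projection is NOT conserved by default: a canonical thermal ensemble
    # of an open-shell system mixes all Sz sectors, and a purification of it is
    # unreachable from the product reference inside one global-Sz block.
    conserve_sz: str = "none"  # "none" | "global" | "per_register"
    distinct_spatial_only: bool = False
    dedupe: bool = True
    include_singles: bool = True
    include_doubles: bool = True


def _spin_of(g: int, m_sys: int) -> int:
    local = g if g < m_sys else g - m_sys
    return local % 2  # 0 = alpha, 1 = beta


def _register_of(g: int, m_sys: int) -> int:
    return 0 if g < m_sys else 1


def _spatial_of(g: int, m_sys: int) -> Tuple[int, int]:
    local = g if g < m_sys else g - m_sys
    return (_register_of(g, m_sys), local // 2)


def _single_arrays(basis: SectorBasis, i: int, k: int):
    """Excitation part of a_i^+ a_k on the sector."""
    rows, cols, signs = [], [], []
    bi, bk = 1 << i, 1 << k
    for idx, w in enumerate(basis.states):
        w = int(w)
        if (w & bk) and not (w & bi):
            s = parity_below(w, k)
            w1 = w ^ bk
            s *= parity_below(w1, i)
            rows.append(basis.index_of[w1 | bi])
            cols.append(idx)
            signs.append(s)
    return rows, cols, signs


def _double_arrays(basis: SectorBasis, i: int, j: int, k: int, l: int):
    """Excitation part a_i^+ a_j^+ a_k a_l on the sector (a_l acts first)."""
    rows, cols, signs = [], [], []
    for idx, w in enumerate(basis.states):
        w = int(w)
        s = 1
        ok = True
        for ann in (l, k):
            b = 1 << ann
            if not (w & b):
                ok = False
                break
            s *= parity_below(w, ann)
            w ^= b
        if not ok:
            continue
        for crt in (j, i):
            b = 1 << crt
            if w & b:
                ok = False
                break
            s *= parity_below(w, crt)
            w |= b
        if not ok:
            continue
        rows.append(basis.index_of[w])
        cols.append(idx)
        signs.append(s)
    return rows, cols, signs


def _finalize(kind, indices, basis, rows, cols, signs) -> Optional[PoolOperator]:
    if not rows and not cols:
        return None  # identically zero on the working sector
    rows = np.asarray(rows, dtype=np.int64)
    cols = np.asarray(cols, dtype=np.int64)
    signs = np.asarray(signs, dtype=np.float64)
    # The generator must decompose into 2x2 rotation blocks for the exact
    # exponential used in fock.apply_exponential: sources and targets of the
    # excitation part must be disjoint and each used at most once.
    assert len(set(rows.tolist())) == len(rows)
    assert len(set(cols.tolist())) == len(cols)
    assert not (set(rows.tolist()) & set(cols.tolist()))
    return PoolOperator(kind, indices, basis, rows, cols, signs)


def build_pool(basis: SectorBasis, cfg: Optional[PoolConfig] = None) -> List[PoolOperator]:
    """Deterministic, duplicate-free restricted pool on a sector.

    Ordering is singles first, then doubles, each block lexicographic in the
    canonicalized index tuples.
    """
    cfg = cfg or PoolConfig()
    M = basis.M
    ms = basis.M_sys
    ops: List[PoolOperator] = []

    if cfg.include_singles:
        for i, k in combinations(range(M), 2):
            if cfg.conserve_register_number and _register_of(i, ms) != _register_of(k, ms):
                continue
            if cfg.conserve_sz in ("global", "per_register") and _spin_of(i, ms) != _spin_of(k, ms):
                continue
            if cfg.distinct_spatial_only and _spatial_of(i, ms) == _spatial_of(k, ms):
                continue
            op = _finalize("single", (i, k), basis, *_single_arrays(basis, i, k))
            if op is not None:
                ops.append(op)

    if cfg.include_doubles:
        pairs = list(combinations(range(M), 2))
        seen = set()
        for ci, (i, j) in enumerate(pairs):
            for k, l in pairs[ci + 1:]:  # (i,j) < (k,l) removes O vs -O duplicates
                if {i, j} == {k, l}:
                    continue
                if cfg.conserve_register_number:
                    nc = (_register_of(i, ms) + _register_of(j, ms))
                    na = (_register_of(k, ms) + _register_of(l, ms))
                    if nc != na:
                        continue
                if cfg.conserve_sz == "global":
                    if _spin_of(i, ms) + _spin_of(j, ms) != _spin_of(k, ms) + _spin_of(l, ms):
                        continue
                elif cfg.conserve_sz == "per_register":
                    balanced = all(
                        sum(_spin_of(g, ms) for g in (i, j) if _register_of(g, ms) == reg)
                        == sum(_spin_of(g, ms) for g in (k, l) if _register_of(g, ms) == reg)
                        for reg in (0, 1)
                    )
                    if not balanced:
                        continue
                if cfg.distinct_spatial_only:
                    spat = [_spatial_of(g, ms) for g in (i, j, k, l)]
                    if len(set(spat)) < len(spat):
                        continue
                key = (i, j, k, l)
                if cfg.dedupe:
                    if key in seen:
                        continue
                    seen.add(key)
                op = _finalize("double", key, basis, *_double_arrays(basis, i, j, k, l))
                if op is not None:
                    ops.append(op)

    if not ops:
        raise ValueError("pool configuration produced an empty pool")
    return ops


def dump_pool(pool: Sequence[PoolOperator], cfg: Optional[PoolConfig] = None) -> str:
    """Human-readable audit listing of a pool (kind, indices, restrictions)."""
    lines = []
    if cfg is not None:
        lines.append(
            f"# conserve_register_number={cfg.conserve_register_number} "
            f"conserve_sz={cfg.conserve_sz} distinct_spatial_only={cfg.distinct_spatial_only} "
            f"dedupe={cfg.dedupe}"
        )
    lines.append(f"# {len(pool)} operators")
    for op in pool:
        lines.append(f"{op.kind:6s} {' '.join(str(i) for i in op.indices):12s} {op.label}")
    return "\n".join(lines) + "\n"


def pool_gradients(
    pool: Sequence[PoolOperator],
    psi: StateVector,
    target,
    p: Optional[int] = None,
) -> np.ndarray:
    """Exact d/dtheta of the squared distance at theta = 0 for every generator.

    For generator O the derivative of ``D(exp(theta O) psi)`` at 0 is
    ``2 Re <g | O psi>`` with ``g`` the Wirtinger gradient of D with respect
    to the conjugate state (computed in :mod:`ensrep.rdm`).
    """
    from .rdm import distance_state_gradient

    _, g = distance_state_gradient(psi, target)
    amp = psi.amplitudes
    out = np.empty(len(pool))
    for m, op in enumerate(pool):
        val = np.sum(op.signs * (np.conj(g[op.rows]) * amp[op.cols]
                                 - np.conj(g[op.cols]) * amp[op.rows]))
        out[m] = 2.0 * val.real
    return out
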