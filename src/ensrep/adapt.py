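"""Adaptive variational minimization of the distance to a target p-RDM.

The loop grows a product ansatz ``|psi(theta)> = prod_m exp(theta_m O_m)|psi_0>``
one generator at a time: at each macro-iteration the pool generator with the
largest exact distance gradient at theta = 0 is appended (earliest pool
position wins ties) and *all* accumulated angles are re-optimized with a
quasi-Newton method using analytic gradients.  Convergence of the squared
Hilbert-Schmidt distance to numerical zero certifies that the target is
(pure or ensemble, depending on the search space) N-representable; otherwise
the converged distance measures the violation and the evolved p-RDM is the
nearest representable matrix found.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from .fock import StateVector, exp_apply_amplitudes
from .pool import PoolOperator, pool_gradients
from .rdm import ReducedDensityMatrix, distance_state_gradient, distance_to_target

__all__ = ["AdaptSettings", "AdaptResult", "optimize_parameters", "adapt_run", "classify"]


@dataclass
class AdaptSettings:
    """Knobs of the adaptive loop.

    ``delta`` is the convergence threshold of the macro-loop (stops when the
    largest pool gradient or the per-iteration distance improvement falls
    below it); ``zero_threshold`` is the distance below which the target is
    declared representable (defaults: 1e-8 for 1-body targets, 1e-7 for
    2-body targets, resolved at run time from the target order).
    """

    delta: float = 5e-9
    max_iterations: int = 200
    optimizer_tol: float = 1e-11
    zero_threshold: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("delta must be positive")

    def resolved_zero_threshold(self, p: int) -> float:
        if self.zero_threshold is not None:
            return self.zero_threshold
        return 1e-8 if p == 1 else 1e-7


@dataclass
class AdaptResult:
    d_min: float
    operators: List[str]
    thetas: np.ndarray
    evolved_rdm: ReducedDensityMatrix
    trace: List[Tuple[int, str, float, float]]  # (iter, label, |grad|, distance)
    converged: bool
    reason: str  # gradient_small | distance_stall | max_iter | exact_zero
    final_state: Optional[StateVector] = field(default=None, repr=False)

    def trace_csv(self) -> str:
        lines = ["iteration,operator,gradient,distance"]
        for it, lab, g, d in self.trace:
            lines.append(f"{it},{lab},{g:.6e},{d:.17e}")
        return "\n".join(lines) + "\n"


def _evolve(psi0: StateVector, operators: Sequence[PoolOperator], thetas) -> StateVector:
    amp = psi0.amplitudes
    for op, th in zip(operators, thetas):
        amp = exp_apply_amplitudes(op, float(th), amp)
    return StateVector(psi0.basis, amp)


def _cost_and_grad(
    psi0: StateVector,
    operators: Sequence[PoolOperator],
    thetas: np.ndarray,
    target: ReducedDensityMatrix,
) -> Tuple[float, np.ndarray]:
    """D(theta) and its full gradient by one forward and one adjoint sweep."""
    K = len(operators)
    states = [psi0.amplitudes]
    for op, th in zip(operators, thetas):
        states.append(exp_apply_amplitudes(op, float(th), states[-1]))
    psiK = StateVector(psi0.basis, states[-1])
    D, g = distance_state_gradient(psiK, target)
    grad = np.empty(K)
    lam = g
    for m in range(K - 1, -1, -1):
        op = operators[m]
        # d psi_K / d theta_m = U_K ... U_{m+1} O_m psi_m, so the chain rule
        # contracts the back-propagated adjoint with O_m applied to psi_m.
        opsi = np.zeros_like(states[m + 1])
        opsi[op.rows] += op.signs * states[m + 1][op.cols]
        opsi[op.cols] -= op.signs * states[m + 1][op.rows]
        grad[m] = 2.0 * np.real(np.vdot(lam, opsi))
        lam = exp_apply_amplitudes(op, -float(thetas[m]), lam)
    return D, grad


def optimize_parameters(
    psi0: StateVector,
    operators: Sequence[PoolOperator],
    thetas0: Sequence[float],
    target: ReducedDensityMatrix,
    p: Optional[int] = None,
    tol: float = 1e-11,
) -> Tuple[np.ndarray, float, bool]:
    """Re-optimize all rotation angles; never returns a worse point than the start."""
    thetas0 = np.asarray(thetas0, dtype=float)
    if len(thetas0) != len(operators):
        raise ValueError("angle vector and operator list have different lengths")
    if len(operators) == 0:
        D, _ = distance_state_gradient(psi0, target)
        return thetas0, D, True
    f0, _ = _cost_and_grad(psi0, operators, thetas0, target)
    res = minimize(
        lambda th: _cost_and_grad(psi0, operators, th, target),
        thetas0,
        jac=True,
        method="BFGS",
        options={"gtol": tol, "maxiter": 2000},
    )
    if res.fun <= f0:
        return res.x, float(res.fun), bool(res.success)
    return thetas0, float(f0), False


def _pool_curvatures(
    pool: Sequence[PoolOperator],
    psi: StateVector,
    target: ReducedDensityMatrix,
    h: float = 1e-3,
) -> np.ndarray:
    """Diagonal curvature d^2 D / d theta^2 at theta = 0 for every generator.

    Used to escape first-order stationary points: a determinant initial state
    whose p-RDM differs from a diagonal target only on the diagonal makes every
    pool gradient vanish identically, while descent directions still exist at
    second order.
    """
    D0 = distance_to_target(psi, target)
    out = np.empty(len(pool))
    for m, op in enumerate(pool):
        amp_p = exp_apply_amplitudes(op, h, psi.amplitudes)
        amp_m = exp_apply_amplitudes(op, -h, psi.amplitudes)
        Dp = distance_to_target(StateVector(psi.basis, amp_p), target)
        Dm = distance_to_target(StateVector(psi.basis, amp_m), target)
        out[m] = (Dp + Dm - 2.0 * D0) / h**2
    return out


def _line_minimize(
    psi: StateVector, op: PoolOperator, target: ReducedDensityMatrix
) -> Tuple[float, float]:
    """Best single angle (and distance) for one generator at the current state."""
    from scipy.optimize import minimize_scalar

    def f(th: float) -> float:
        amp = exp_apply_amplitudes(op, float(th), psi.amplitudes)
        return distance_to_target(StateVector(psi.basis, amp), target)

    grid = np.linspace(-np.pi, np.pi, 25, endpoint=False)
    vals = [f(t) for t in grid]
    t0 = float(grid[int(np.argmin(vals))])
    step = float(grid[1] - grid[0])
    res = minimize_scalar(f, bounds=(t0 - step, t0 + step), method="bounded",
                          options={"xatol": 1e-12})
    if res.fun <= min(vals):
        return float(res.x), float(res.fun)
    return t0, float(min(vals))


def _second_order_candidate(
    pool: Sequence[PoolOperator],
    psi: StateVector,
    target: ReducedDensityMatrix,
    delta: float,
    curv: np.ndarray,
    n_candidates: int = 32,
) -> Optional[Tuple[int, float, float]]:
    """Escape direction at a first-order stationary point, or None if truly stuck.

    Among the generators with the most negative diagonal curvature, each
    candidate is line-minimized and the one reaching the lowest distance wins
    (earliest pool position on ties).  Returns (pool index, angle, distance).
    """
    tol = max(delta, 1e-10)
    if float(np.min(curv)) > -tol:
        return None
    order = np.argsort(curv, kind="stable")
    best: Optional[Tuple[float, int, float]] = None
    for m in order[:n_candidates]:
        m = int(m)
        if curv[m] > -tol:
            break
        th, d_line = _line_minimize(psi, pool[m], target)
        if best is None or d_line < best[0] - 1e-12 or (d_line < best[0] + 1e-12 and m < best[1]):
            best = (d_line, m, th)
    return (best[1], best[2], best[0]) if best is not None else None


def _pair_escape(
    pool: Sequence[PoolOperator],
    psi: StateVector,
    target: ReducedDensityMatrix,
    curv: np.ndarray,
    n_candidates: int = 10,
    n_grid: int = 13,
) -> Optional[Tuple[int, float, int, float, float]]:
    """Best coarse two-generator move among the lowest-curvature candidates.

    Some stationary points are minima along every single generator direction
    yet descend along a coupled two-generator rotation; a coarse grid over
    candidate pairs finds such directions deterministically.  Returns
    (index_a, theta_a, index_b, theta_b, distance) or None.
    """
    order = [int(m) for m in np.argsort(curv, kind="stable")[:n_candidates]]
    grid = np.linspace(-np.pi, np.pi, n_grid, endpoint=False)
    best: Optional[Tuple[float, int, float, int, float]] = None
    for ai in range(len(order)):
        for bi in range(ai + 1, len(order)):
            a, b = order[ai], order[bi]
            for ta in grid:
                amp_a = exp_apply_amplitudes(pool[a], float(ta), psi.amplitudes)
                for tb in grid:
                    amp = exp_apply_amplitudes(pool[b], float(tb), amp_a)
                    d = distance_to_target(StateVector(psi.basis, amp), target)
                    if best is None or d < best[0] - 1e-12:
                        best = (d, a, float(ta), b, float(tb))
    if best is None:
        return None
    return best[1], best[2], best[3], best[4], best[0]


def adapt_run(
    psi0: StateVector,
    target: ReducedDensityMatrix,
    pool: Sequence[PoolOperator],
    settings: Optional[AdaptSettings] = None,
) -> AdaptResult:
    """Run the adaptive loop until the distance converges.

    The recorded per-iteration distances are non-increasing by construction:
    each re-optimization starts from the previous optimum with the new angle
    at zero and keeps the incumbent if the local optimizer fails to improve.
    """
    if len(pool) == 0:
        raise ValueError("operator pool is empty")
    settings = settings or AdaptSettings()
    zero = settings.resolved_zero_threshold(target.p)

    operators: List[PoolOperator] = []
    labels: List[str] = []
    thetas = np.zeros(0)
    D, _ = distance_state_gradient(psi0, target)
    trace: List[Tuple[int, str, float, float]] = [(0, "", np.nan, D)]
    reason = "max_iter"
    converged = False

    force_escape = False
    for it in range(1, settings.max_iterations + 1):
        if D < zero:
            reason, converged = "exact_zero", True
            break
        psi_cur = _evolve(psi0, operators, thetas)
        grads = pool_gradients(pool, psi_cur, target)
        gmax = float(np.max(np.abs(grads)))
        theta_init = 0.0
        new_ops: List[Tuple[int, float]] = []
        if gmax >= settings.delta and not force_escape:
            # argmax of |gradient|; ties resolved toward the earliest pool entry
            new_ops = [(int(np.argmax(np.abs(grads) > gmax - 1e-12)), 0.0)]
        else:
            # Either a first-order stationary point, or the gradient step just
            # failed to lower the distance.  Look for a second-order descent
            # direction, then for a coupled two-generator one; only if neither
            # achieves real progress is the run declared converged.
            curv = _pool_curvatures(pool, psi_cur, target)
            escape = _second_order_candidate(pool, psi_cur, target, settings.delta, curv)
            if escape is not None and D - escape[2] >= settings.delta:
                new_ops = [(escape[0], escape[1])]
            else:
                pair = _pair_escape(pool, psi_cur, target, curv)
                if pair is not None and D - pair[4] >= settings.delta:
                    new_ops = [(pair[0], pair[1]), (pair[2], pair[3])]
            if not new_ops:
                reason = "gradient_small" if gmax < settings.delta else "distance_stall"
                converged = True
                break
        for best, theta_init in new_ops:
            operators.append(pool[best])
            labels.append(pool[best].label)
            thetas = np.append(thetas, theta_init)
        thetas, D_new, _ = optimize_parameters(
            psi0, operators, thetas, target, target.p, settings.optimizer_tol
        )
        improvement = D - D_new
        D = min(D, D_new)
        trace.append((it, labels[-1], gmax, D))
        # a step that made no progress routes the next one through the escape scan
        force_escape = improvement < settings.delta
    else:
        it = settings.max_iterations

    psi_final = _evolve(psi0, operators, thetas)
    from .rdm import compute_rdm

    evolved = compute_rdm(psi_final, target.p)
    return AdaptResult(
        d_min=D,
        operators=labels,
        thetas=thetas,
        evolved_rdm=evolved,
        trace=trace,
        converged=converged,
        reason=reason,
        final_state=psi_final,
    )


@dataclass
class Classification:
    label: str  # pure | ensemble_only | not_representable
    pure: AdaptResult
    ensemble: AdaptResult


def classify(
    target: ReducedDensityMatrix,
    reference_occupation=None,
    settings: Optional[AdaptSettings] = None,
    pool_config=None,
) -> Classification:
    """Decide pure vs ensemble N-representability of an alleged p-RDM.

    Runs the adaptive minimization twice: on the bare N-electron system space
    (pure test) and on the purified system+bath space with the product initial
    state (ensemble test).  ``reference_occupation`` is the list of occupied
    :class:`~ensrep.fock.SpinOrbital` of the reference determinant; by default
    the lowest N spin-orbitals are occupied.
    """
    from .fock import SpinOrbital, build_sector_basis, slater_determinant
    from .pool import PoolConfig, build_pool
    from .states import purify_product

    settings = settings or AdaptSettings()
    M, N = target.M_sys, target.N
    sys_basis = build_sector_basis(M, 0, N, 0)
    if reference_occupation is None:
        reference_occupation = [
            SpinOrbital.from_global_index(g, M) for g in range(N)
        ]
    phi0 = slater_determinant(sys_basis, reference_occupation)

    cfg = pool_config or PoolConfig()
    pure_pool = build_pool(sys_basis, cfg)
    pure_res = adapt_run(phi0, target, pure_pool, settings)

    psi0 = purify_product(phi0)
    ens_pool = build_pool(psi0.basis, cfg)
    ens_res = adapt_run(psi0, target, ens_pool, settings)

    zero = settings.resolved_zero_threshold(target.p)
    if pure_res.d_min < zero:
        label = "pure"
    elif ens_res.d_min < zero:
        label = "ensemble_only"
    else:
        label = "not_representable"
    return Classification(label, pure_res, ens_res)
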