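# ensrep

**Pure and ensemble N-representability testing of fermionic reduced density
matrices by adaptive variational unitary evolution.**

A p-body reduced density matrix (p-RDM) is *N-representable* when some
N-electron state has it as its p-particle marginal — *pure* if a single wave
function suffices, *ensemble* if a convex mixture is needed.  Deciding this
is a foundational problem of electronic-structure theory: for p = 1 the
answer is classical (Coleman's conditions for ensembles, Klyachko's
generalized Pauli constraints for pure states), while for p = 2 no complete
pure-state criterion is known.

`ensrep` settles the question *constructively*.  It evolves a statevector
|psi(θ)> = Π_m exp(θ_m O_m)|psi_0> through an adaptively grown sequence of
one- and two-body rotations O_m, minimizing the squared Hilbert–Schmidt
distance

    D(θ) = || rho_p(psi(θ)) − rho_target ||_F² .

For a **pure** test, psi lives in the bare N-electron Fock sector.  For an
**ensemble** test, psi lives on a doubled register (system ⊗ bath) and the
target is compared against the bath-traced marginal: by the purification
theorem, an ensemble exists iff a pure state on the doubled space matches
the target, so the same machinery answers both questions.  A converged
D_min ≈ 0 certifies representability; otherwise D_min measures the
violation and the evolved rho_p is the nearest physical RDM found — a
density-matrix *repair*, not just a verdict.

Audience: electronic-structure and quantum-information researchers who need
to check, classify or correct RDMs from quantum simulations, tomography or
reduced-density-matrix methods.

## Worked example

Classify the 1-RDM of the equal mixture of the four-electron determinants
|1α 1β 2α 2β⟩ and |1α 1β 3α 2β⟩ on 4 spatial orbitals:

```python
import numpy as np
from ensrep import MixtureSpec, classify, mixture_target
from ensrep.fock import so

rho1 = [so(1, "alpha"), so(1, "beta"), so(2, "alpha"), so(2, "beta")]
rho2 = [so(1, "alpha"), so(1, "beta"), so(3, "alpha"), so(2, "beta")]
target = mixture_target(MixtureSpec.two_state(rho1, rho2, 0.5), p=1, M_sys=8)

print("occupations:", np.round(target.eigenvalues(), 3))
out = classify(target, reference_occupation=rho1)
print(out.label)
print("pure     D_min =", f"{out.pure.d_min:.3e}")
print("ensemble D_min =", f"{out.ensemble.d_min:.3e}")
```

prints

```
occupations: [1.  1.  1.  0.5 0.5 0.  0.  0. ]
ensemble_only
pure     D_min = 1.250e-01
ensemble D_min = 2.465e-32
```

The half-filled occupation pair violates the generalized Pauli constraints,
so no single wave function can produce this matrix: the pure search bottoms
out at D_min = 0.125, while the purified (ensemble) search drives the
distance to numerical zero.  The matrix is ensemble-only representable, and
`out.pure.evolved_rdm` holds the closest pure-state 1-RDM.

The same loop handles 2-RDMs, canonical thermal targets for H2 and linear
H3 in a minimal basis (built from in-package STO-3G integrals or any
FCIDUMP), and noise-perturbed matrices, e.g.

```
ensrep run fixtures/t7/t7_h3_r0.75_p2_eps0_s0.yaml --output-dir results
ensrep classify --rdm my_matrix.rdm --p 1 --n-electrons 4 --orbitals 4
ensrep table t2 --results-dir results --run-missing
ensrep fixtures --out-dir fixtures
```

`ensrep table` renders a computed-vs-published comparison for the bundled
benchmark grids (determinant mixtures, substitution families, noisy targets,
thermal molecules).

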