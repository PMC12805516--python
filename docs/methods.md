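# Methods

## Problem

Given an alleged p-body reduced density matrix (p-RDM, p = 1 or 2) of an
N-electron system, decide whether it is the marginal of (i) a single
N-electron wave function (*pure* N-representability), (ii) a convex mixture
of such wave functions (*ensemble* N-representability), or (iii) neither —
and in every case produce the closest physical p-RDM found.  The decision
is made variationally: a statevector is evolved by a growing product of
one- and two-body rotations so as to minimize the squared Hilbert-Schmidt
distance

    D = || rho_p(psi) - rho_target ||_F^2 ,

and the converged minimum D_min is the representability verdict (zero means
representable; otherwise D_min measures the violation and the evolved RDM is
the nearest physical matrix the search found).

## State space and purification

Pure tests run on the determinant basis of the N-electron sector of M
system spin-orbitals.  Ensemble tests exploit the Schrödinger–HJW purification
theorem: every ensemble on the system is the bath-trace of a pure state on a
doubled register (bath a copy of the system, N bath electrons).  The initial
state of an ensemble run is always the unentangled product
|phi_0> ⊗ |phi_0> of the reference determinant with its bath mirror; the
algorithm must *discover* the entangled purification.  RDMs are always taken
over system orbitals only, so the bath is traced out implicitly, and carry
the quantum-chemistry normalization tr(rho_p) = p! C(N, p).

Spin-orbital ordering is frozen (system register before bath; spatial index
ascending; alpha before beta) and all fermionic signs are parities of
occupation bitstrings under that ordering — the Jordan-Wigner convention for
this register layout.  Distances are invariant to this choice; fixing it
makes amplitudes reproducible.

## Operator pool

Generators are antihermitian excitation–deexcitation combinations
O_ik = a_i†a_k − a_k†a_i and O_ijkl = a_i†a_j†a_k a_l − a_k†a_l†a_i a_j,
restricted so that no generator changes the electron count of the system
register or of the bath register (the canonical-ensemble restriction).  No
spin-projection restriction is imposed by default: a canonical thermal
ensemble of an open-shell molecule (linear H3) populates all Sz sectors, and
its purification is unreachable from the product reference inside a single
global-Sz block — an Sz-conserving pool stalls at D ~ 1e-1 on the H3 2-RDM
thermal target where the unrestricted pool converges below 1e-8.  Optional
toggles (`conserve_sz="global"` / `"per_register"`, spatial-distinctness,
singles/doubles switches) expose stricter rules.

With register-number conservation alone the pools on 8 / 12 / 16 extended
spin-orbitals contain 162 / 870 / 2828 generators.  Published counts for the
same settings are 72 / 378 / 1196; the precise counting rule behind those
numbers (index canonicalization, spin handling) is not recoverable from the
stated restriction, so pool sizes are logged and compared informationally,
never enforced.

Every generator, stored as the index/sign arrays of its excitation part, is
a signed partial permutation whose antisymmetry decomposes it into
independent 2×2 rotation blocks, so O³ = −O and

    exp(θO) = 1 + sin(θ) O + (1 − cos(θ)) O²

is exact — no Trotterization and no matrix exponential is ever needed.  The
block structure is asserted at pool-construction time.

## Adaptive loop

Each macro-iteration appends one generator and re-optimizes *all* angles
(BFGS with analytic gradients; one forward and one adjoint sweep per
evaluation, so the cost is linear in the ansatz depth).  Selection is by the
largest exact gradient d D/dθ at θ = 0, computed for the whole pool from a
single Wirtinger gradient state; ties go to the earliest pool position, and
a newly appended angle starts at 0.  The loop stops when the distance falls
below `zero_threshold` (1e-8 for p = 1, 1e-7 for p = 2 by default), when no
descent direction remains (below), or at `max_iterations`.  Recorded traces
are non-increasing by construction: the re-optimizer never returns a worse
point than its start.

**Stationary-point escapes.**  The initial determinant is a *first-order
stationary point* for every benchmark target here: the RDM mismatch at a
determinant against a determinant-mixture target is diagonal, which makes
every pool gradient vanish identically while descent directions exist at
second order.  Gradient selection alone therefore cannot even start, and
greedy fixes (picking the most negative diagonal curvature) demonstrably
descend into spurious basins.  The loop therefore escalates deterministically
whenever the pool gradient *or* the last distance improvement drops below
the threshold δ:

1. diagonal curvatures d²D/dθ²|₀ are computed for the pool (central
   differences of the exact distance, step 1e-3); among the 32 most negative
   the generator whose *line-minimized* distance is lowest is appended, with
   its line-optimal angle as the start;
2. if no single generator achieves progress ≥ δ, coarse two-generator grid
   scans (13×13 angles over the 10 lowest-curvature candidates) look for a
   coupled escape — some traps are minima along every single generator
   direction yet descend under a paired rotation;
3. only when both stages fail is the run declared converged
   (`gradient_small` at a true stationary point, `distance_stall` otherwise).

With these escapes the loop reproduces, from the prescribed determinant
starts, the known minima 1.25e-1 (1-RDM) and 2.00 / 4.25 (2-RDMs) that a
brute-force statevector minimization finds from generic starts, and the
same brute-force cross-check is part of the test suite on a two-electron
system.  Because the one/two-body generators are real rotations, a real
reference can only reach real amplitudes; this is irrelevant for the
physical targets here (all real symmetric) but means complex-phase targets
are tested against the real-restricted optimum.

## Audits

Coleman's ensemble conditions (1-RDM eigenvalues in [0, 1], trace N, checked
at tolerance 1e-8) are necessary and sufficient for 1-RDM ensemble
representability and are reported alongside every run.  Pure-state
(generalized Pauli / Klyachko) constraints for N = 4, M = 8 are shipped as a
plain-text data file of 15 affine inequalities on the descending spectrum.
The list was reconstructed numerically in this project by *certified
projections*: for a probe point x outside the polytope of sorted pure-state
spectra, minimizing ||rho_1(psi) − diag(x)||² over the 70-dimensional pure
sector is a smooth problem whose optimal spectrum mu is the Euclidean
projection of x onto the polytope, so x − mu is a supporting normal by the
projection theorem for convex sets.  Shell probes around the polytope
produced exactly sixteen integer normals (saturated over many hundreds of
further probes): the trivial facets lambda_1 ≤ 1 and lambda_8 ≥ 0, and
fourteen generalized Pauli constraints forming seven particle-hole-dual
pairs — the self-duality expected for N = M/2.  Every facet was re-certified
by push-out projection tests (a point moved eps off a facet foot projects
back to that foot at distance eps²) and by Monte-Carlo sampling of pure
spectra (no violations).  The shipped list contains the fourteen
generalized Pauli constraints plus the Pauli bound lambda_1 ≤ 1; the
remaining facet, lambda_8 ≥ 0, is already part of the Coleman audit.
Spectra of systems with fewer than 8 spin-orbitals are zero-padded before
evaluation, a state on fewer orbitals being also a state on 8.

## Thermal targets

Molecular targets are canonical-ensemble averages Σ w_i ρ_p(v_i) with
Boltzmann weights w_i ∝ exp(−E_i/kT) over *all* eigenstates of the
N-electron sector of H = Σ h_pq a_p†a_q + ¼ Σ ⟨pq||rs⟩ a_p†a_q†a_s a_r
(no spin sub-ensemble restriction: the canonical ensemble fixes particle
number only).  kT defaults to the gap between the ground level and the first
*distinct* level above it (tolerance 1e-8 Hartree); the literal first-excited
gap is zero for H3's degenerate ground doublet.  Geometries are H2 and
linear, equally spaced H3 at adjacent separations 0.75 Å and 1.5 Å.

Integrals are minimal-basis STO-3G, computed in-package with the closed-form
s-shell Gaussian formulas (Boys function F0) and validated against classic
published H2 values (overlap, kinetic, repulsion integrals at R = 1.4 bohr to
4 decimals; FCI ground energy −1.13728 Hartree).  Orbitals are the canonical
eigenvectors of the core Hamiltonian under the overlap metric — identical to
restricted Hartree-Fock for minimal-basis H2 by symmetry, symmetry-adapted
for linear H3 — and the mean-field reference determinant occupies the lowest
N spin-orbitals.  A second, independently coded Slater–Condon oracle checks
the sector Hamiltonian in the tests.  FCIDUMP files (chemist notation,
8-fold symmetry) round-trip through the bundled reader/writer and fixture
files for the four (molecule, geometry) cases are regenerated bit-identically
by `ensrep fixtures`.

## Noise model

Defective targets are built as rho + ε·R with R elementwise uniform in
[−1, 1] and ε ∈ {0, 1e-2, 1e-1}.  By default R is Hermitized
(R ← (R + Rᵀ)/2) so the target stays a valid Hermitian matrix;
`hermitize_noise: false` keeps the raw draw, whose antihermitian part adds an
irreducible ε²-scale floor to the distance (the published ε = 0.1 values
match that raw-noise floor: ε²d²/3 ≈ 0.213 for the 8×8 1-RDM, ≈ 13.7 for the
64×64 2-RDM).  Because the published noisy minima depend on an unpublished
noise realization, noisy cells are compared by order of magnitude, with the
median over 5 seeds, and the monotonicity of D_min in ε is the tested
property.

## Numerical choices

* Optimizer: BFGS, gradient tolerance 1e-11 by default, never accepting an
  uphill result; angles are unconstrained (the cost is 2π-periodic per
  angle).
* Convergence threshold δ defaults to 5e-9 (the strict end of the published
  range [5e-9, 3e-5]); noisy and two-body scenarios may raise it through
  scenario settings.
* Degeneracy tie-breaks (operator selection, thermal level grouping) are
  resolved toward the earliest index, making every run bit-reproducible;
  no randomness is consumed anywhere in the default pipeline, so seeds only
  label noise realizations.
* Dense sector dimensions stay ≤ 4900 (the purified (4e,4o) problem); all
  operator applications are index-gather/scatter operations, never matrix
  products against the full sector.

## Problem sizes used in validation

The bundled test-suite and acceptance runs use the model systems exactly at
their published sizes — (4e,3o) and (4e,4o), purified sectors of dimension
225 and 4900 — and the H2/H3 thermal systems at STO-3G size.  Noise-
monotonicity checks run on the H2 thermal system (purified dimension 36),
where 5-seed medians per ε are cheap; the larger noisy model cells are
exercised through the scenario CLI rather than the default test run.

## Known limitations

* The search is non-convex: D_min is an upper bound on the true distance to
  the representable set.  The escape machinery removes every trap observed
  on the benchmark targets, but global optimality is not certified.
* Generalized Pauli constraint data is bundled only for (N, M) = (4, 8).
* p ≥ 3 RDMs, spin-adapted blocks, cumulant decompositions and
  qubit-circuit emission are out of scope.
* The integral engine covers s-type shells (hydrogen chains in minimal
  basis); other elements or basis sets must come through FCIDUMP input.
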