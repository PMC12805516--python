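# Pure-state (generalized Pauli) constraints on the descending natural
# occupation numbers of 4 fermions in 8 spin-orbitals, plus the basic
# Pauli bound lambda_1 <= 1 (15 inequalities; the remaining facet of the
# spectral polytope, lambda_8 >= 0, is part of the Coleman conditions).
# Reconstructed and certified numerically: each plane is the foot-normal
# of certified projections onto the pure-spectrum polytope, re-verified
# by push-out projection tests and Monte-Carlo sampling.
# Format: 8 integer coefficients on the sorted eigenvalues, '<=', bound.
4 8
 1  1  1 -1  0  0  0  0  <=  2
 1  1  0  0  1 -1  0  0  <=  2
 1  1  0  0  0  0  1 -1  <=  2
 1  0  1  0  1  0 -1  0  <=  2
 1  0  1  0  0  1  0 -1  <=  2
 1  0  0  1  1  0  0 -1  <=  2
 0  1  1  0  1  0  0 -1  <=  2
 1  0  0  0  0  0  0  0  <=  1
 1  0  0 -1  0 -1 -1  0  <=  0
 1  0  0 -1 -1  0  0 -1  <=  0
 1  0 -1  0  0 -1  0 -1  <=  0
 1 -1  0  0  0  0 -1 -1  <=  0
 0  1  0 -1  0 -1  0 -1  <=  0
 0  0  1 -1  0  0 -1 -1  <=  0
 0  0  0  0  1 -1 -1 -1  <=  0
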