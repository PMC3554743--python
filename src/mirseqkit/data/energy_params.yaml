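# Nearest-neighbour free-energy parameters (kcal/mol) for hairpin scoring.
# Turner-like stacking values for the six canonical/wobble pairs; loop
# closure penalties tabulated by size with logarithmic extrapolation.
# The matrix satisfies the thermodynamic symmetry
#   stack[x][y] == stack[reverse(y)][reverse(x)].
stack:
  AU: {AU: -0.9, CG: -2.2, GC: -2.1, UA: -1.1, GU: -0.6, UG: -1.4}
  CG: {AU: -2.1, CG: -3.3, GC: -2.4, UA: -2.1, GU: -1.4, UG: -2.1}
  GC: {AU: -2.4, CG: -3.4, GC: -3.3, UA: -2.2, GU: -1.5, UG: -2.5}
  UA: {AU: -1.3, CG: -2.4, GC: -2.1, UA: -0.9, GU: -1.0, UG: -1.3}
  GU: {AU: -1.3, CG: -2.5, GC: -2.1, UA: -1.4, GU: -0.5, UG: 1.3}
  UG: {AU: -1.0, CG: -1.5, GC: -1.4, UA: -0.6, GU: 0.3, UG: -0.5}
# Hairpin-loop closure penalty by number of unpaired loop bases (min 3).
hairpin:
  {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
hairpin_extrapolation: 1.1   # penalty(L) = penalty(9) + c * ln(L/9) for L > 9
# Bulge-loop penalty by number of unpaired bases on the bulged side.
bulge:
  {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
bulge_extrapolation: 1.1
# Internal-loop penalty by total unpaired bases (both sides).
internal:
  {2: 4.1, 3: 5.1, 4: 4.9, 5: 5.3, 6: 5.7, 7: 5.9, 8: 6.1, 9: 6.3, 10: 6.5, 11: 6.7, 12: 6.9}
internal_extrapolation: 1.1
# Interior (bulge + internal) loops with more unpaired bases than this are
# disallowed entirely (part of the model, applied identically by the DP and
# by any loop-decomposition rescoring).
max_interior: 12
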