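# Dissolution-rate parameter sets for the transition-state-theory rate law
#   r = k * a_H+^n_H * exp(-Ea / (R T)) * f(dG),   f(dG) = 1 - exp(dG / (R T))
#
# forsterite: alkaline-mechanism olivine parameters in the published form
#   log10 r = 4.07 - 0.26 pH - 3464 / T
# The Arrhenius temperature A_T = Ea / (R ln 10) = 3464 K is authoritative
# (the rounded Ea = 66 kJ/mol variant systematically overestimates rates by
# ~12%); Ea below is stored as the exact equivalent of A_T.
#
# basaltic_glass: hydrated basaltic glass, far-from-equilibrium parameters.

forsterite:
  log10_k: 4.07          # mol m-2 s-1
  n_H: 0.26
  arrhenius_T_K: 3464.0  # A_T = Ea / (R ln10)
  pH_valid: [5.6, 14.0]
  T_valid_C: [0.0, 150.0]

basaltic_glass:
  k: 3.57e-5             # mol m-2 s-1
  n_H: -0.39
  Ea_J_mol: 41000.0
  pH_valid: [0.0, 14.0]
  T_valid_C: [0.0, 150.0]
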