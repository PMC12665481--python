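# Reduced thermodynamic database for basalt-hosted groundwater speciation.
#
# Each reaction carries a log10 K grid on a common temperature grid (deg C);
# values between grid points are interpolated linearly in T. The grids are
# editable defaults with literature-magnitude values (SUPCRT/PHREEQC-style
# compilations); they drive the full-speciation mode only, never the
# printed-input ("mode A") computations.
#
# Conventions:
#   water:        H2O = H+ + OH-                      (log K = -pKw)
#   carbonate_1:  H2CO3* = H+ + HCO3-                 (log K = -pK1)
#   carbonate_2:  HCO3-  = H+ + CO3--                 (log K = -pK2)
#   sulfide_1:    H2S(aq) = H+ + HS-                  (log K = -pKa1)
#   silicic_1:    H4SiO4 = H+ + H3SiO4-               (log K = -pKa1)
#   forsterite:   Mg2SiO4 + 4 H+ = 2 Mg++ + SiO2(aq) + 2 H2O
#   basaltic_glass: SiAl0.35O2(OH)1.05 + 1.05 H+ = SiO2(aq) + 0.35 Al+++ + 1.05 H2O
#                 (hydrated basaltic glass proxy composition)
#   sulfate_sulfide: SO4-- + 10 H+ + 8 e- = H2S(aq) + 4 H2O   (reduction, SHE)
#
# davies_A is the Debye-Hueckel A parameter (kg^0.5 mol^-0.5) used by the
# Davies activity model.

temperature_grid_C: [20, 25, 40, 60, 80, 100, 115]

log_k:
  water:           [-14.163, -13.995, -13.535, -13.034, -12.609, -12.259, -12.040]
  carbonate_1:     [-6.38, -6.35, -6.30, -6.29, -6.34, -6.42, -6.50]
  carbonate_2:     [-10.38, -10.33, -10.22, -10.14, -10.13, -10.16, -10.20]
  sulfide_1:       [-7.05, -6.98, -6.82, -6.68, -6.61, -6.59, -6.60]
  silicic_1:       [-9.93, -9.84, -9.60, -9.35, -9.15, -8.98, -8.88]
  forsterite:      [29.1, 28.6, 27.2, 25.5, 24.0, 22.7, 21.9]
  basaltic_glass:  [8.10, 8.00, 7.70, 7.30, 6.90, 6.55, 6.30]
  sulfate_sulfide: [41.4, 40.6, 38.3, 35.6, 33.3, 31.3, 30.0]

davies_A: [0.5046, 0.5092, 0.5241, 0.5450, 0.5706, 0.5998, 0.6240]
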