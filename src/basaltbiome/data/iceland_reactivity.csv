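well_id,dG_Fo_kJ_mol,dG_BG_kJ_mol,pH_T,EH_V,r_Fo_mol_m2_s,r_BG_mol_m2_s
M22-1,-24.8,-15.1,7.3,-0.31,1.26e-7,6.22e-8
M22-2,-25.4,-13.6,7.5,-0.32,6.03e-8,5.08e-8
M22-3,-26.1,-15.0,8.8,-0.45,2.06e-8,1.36e-7
M22-4,-20.5,-15.6,8.7,-0.42,1.26e-8,8.85e-8
M22-5,-26.8,-15.0,9.1,-0.44,4.00e-9,7.21e-8
M22-6,-17.4,-14.8,9.0,-0.43,4.53e-9,6.88e-8
M22-7,-38.0,-13.6,7.9,-0.35,2.46e-8,4.84e-8
M22-8,-32.3,-12.1,8.7,-0.40,3.86e-9,4.25e-8
M22-9,-25.4,-13.4,9.1,-0.42,1.85e-9,4.48e-8
M22-10,-9.5,-16.0,8.7,-0.46,5.47e-8,2.26e-7
M22-11,-12.4,-15.7,8.8,-0.44,2.42e-8,1.52e-7
O22-1,-11.4,-12.7,9.3,-0.45,3.73e-9,9.00e-8
O22-2,-10.2,-12.4,9.4,-0.45,2.65e-9,8.32e-8
O22-3,-0.9,-15.9,9.9,-0.49,4.33e-10,1.15e-7
O22-4,n.d.,n.d.,9.7,n.d.,3.00e-10,3.12e-8
O22-5,-0.9,-13.6,9.5,-0.46,5.89e-10,8.35e-8
O22-6,n.d.,n.d.,9.6,-0.46,1.96e-9,8.75e-8
O22-7,-15.3,-9.9,9.3,-0.43,1.52e-9,5.13e-8
O22-8,n.d.,n.d.,9.4,-0.48,1.13e-8,2.01e-7
O22-9,-27.6,-7.2,9.0,-0.35,1.97e-10,9.88e-9
O22-10,-12.7,-11.2,8.6,-0.41,1.60e-8,9.08e-8
O22-11,n.d.,n.d.,6.3,n.d.,1.52e-8,4.72e-9
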