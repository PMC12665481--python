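well_id,T_C,pH_20C,cond_mS_cm,O2aq_ppm,DOC_ppm,TN_ppm,H2S_ppm,SiO2_ppm,B_ppm,Na_ppm,K_ppm,Ca_ppm,Mg_ppm,Al_ppm,Fe_ppm,Cl_ppm,F_ppm,CO2_ppm,SO4_ppm
M22-1,109,8.3,7.15,3.2,0.32,n.d.,0.09,102,0.192,734,21,676,0.776,0.019,0.098,2054,0.67,4.5,252
M22-2,98,8.4,4.71,2.1,0.68,n.d.,0.18,111,0.180,576,17,405,0.627,0.020,0.079,1491,0.74,5.5,188
M22-3,93,9.9,0.38,2.7,0.41,n.d.,0.26,108,0.028,45,1.35,2.6,0.001,0.161,0.001,22,0.42,26.4,14
M22-4,84,9.6,0.23,2.9,0.38,n.d.,0.03,46,0.012,42,0.73,3.5,0.013,0.159,0.002,30,0.16,25.7,12
M22-5,70,9.7,0.18,3.9,0.29,n.d.,0.14,49,0.018,33,0.49,2.7,0.003,0.099,0.057,15,0.26,21.2,12
M22-6,71,9.8,0.22,2.9,0.29,n.d.,0.38,59,0.029,41,0.65,3.7,0.015,0.097,0.009,18,0.46,31,17
M22-7,87,8.8,0.90,2.2,0.16,n.d.,0.57,99,0.175,155,4.76,15,0.016,0.018,0.002,207,1.90,21.6,64
M22-8,66,9.3,0.42,3.7,0.33,n.d.,1.15,102,0.255,80,2.04,3.9,0.008,0.027,0.006,48,2.94,32.7,51
M22-9,59,9.8,0.54,4.0,0.28,n.d.,0.29,68,0.156,93,1.58,7.9,0.009,0.044,0.003,95,2.58,10.1,53
M22-10,110,10.0,0.29,2.2,0.09,n.d.,0.34,142,0.048,61,2.32,2.9,0.007,0.215,0.005,43,0.73,17.7,19
M22-11,96,9.8,0.45,2.2,0.19,n.d.,0.15,106,0.250,98,1.86,2.8,0.016,0.118,n.d.,49,0.92,20.1,67
O22-1,71,10.6,0.27,0.5,0.40,< 0.1,0.14,113,0.083,50,0.85,2.3,0.015,0.354,0.012,10,1.04,13.4,73
O22-2,67,10.6,0.27,0.6,0.13,< 0.1,0.20,120,0.083,52,0.79,2.0,0.017,0.355,0.034,10,0.99,12.7,71
O22-3,64,11.0,0.26,0.8,0.22,< 0.1,0.10,82,0.083,44,0.56,2.3,0.022,0.549,0.02,5,0.71,11.7,40
O22-4,40,10.2,0.19,0.6,0.62,< 0.1,0.07,74,0.062,41,0.21,2.4,0.010,0.018,n.d.,n.d.,n.d.,19.1,n.d.
O22-5,65,10.6,0.27,0.7,0.23,< 0.1,0.14,90,0.285,50,0.59,2.4,0.070,0.371,0.018,18,1.50,20.4,57
O22-6,64,10.3,0.30,n.d.,n.d.,n.d.,0.14,79,0.206,53,0.90,3.7,0.091,0.298,0.013,18,1.40,12.5,139
O22-7,58,9.9,0.27,0.6,0.32,< 0.1,0.44,130,0.454,71,2.05,2.4,0.032,0.370,0.022,14,1.04,31.1,160
O22-8,89,10.4,0.38,0.8,1.47,1.16,0.17,75,0.188,49,0.81,3.5,0.032,0.317,0.012,28,2.20,11.8,121
O22-9,30,9.1,0.47,0.7,0.29,< 0.1,0.10,46,0.129,81,3.71,6.7,0.312,0.258,0.011,20,0.10,50.9,151
O22-10,87,9.6,0.36,0.4,0.61,< 0.1,0.22,164,0.252,69,2.37,3.2,0.061,0.347,0.024,18,1.10,45,163
O22-11,65,7.0,1.52,0.5,0.23,< 0.1,n.d.,192,0.223,n.d.,10,23,0.227,0.027,0.587,n.d.,n.d.,n.d.,n.d.
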