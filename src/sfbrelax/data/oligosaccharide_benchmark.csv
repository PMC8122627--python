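system,probe_type,solvent,temperature_K,viscosity_Pa_s,freq_MHz,reff_A,T1_exp_ms,T1_calc_ms,T2_exp_ms,T2_calc_ms,NOE_exp,NOE_calc,e_T1_ref,e_T2_ref,e_NOE_ref
R2R,CH,DMSO-d6,298.2,2.19e-3,600.1,1.6,440.0,449.9,402.6,420.5,2.361,2.308,2.3,4.4,2.3
R2R,CH,DMSO-d6,298.2,2.19e-3,700.0,1.6,475.6,497.5,432.9,456.1,2.215,2.150,4.6,5.4,2.9
BGL,CH2,DMSO-d6/D2O 7:3,253,2.82e-2,400,1.8,150,177,32.5,31.4,1.03,1.22,17.8,3.2,18.5
BGL,CH2,DMSO-d6/D2O 7:3,253,2.82e-2,600,1.8,284,344,30.1,33.1,1.08,1.21,21.1,10.1,12.2
BGL,CH2,DMSO-d6/D2O 7:3,263,1.42e-2,400,1.8,117,121,48.0,53.7,1.19,1.26,3.6,11.8,5.9
BGL,CH2,DMSO-d6/D2O 7:3,263,1.42e-2,600,1.8,205,219,55.0,61.0,1.10,1.23,6.9,10.9,12.1
BGL,CH2,DMSO-d6/D2O 7:3,293,4.30e-3,400,1.8,127,124,106,107,1.86,1.78,2.0,1.0,4.5
BGL,CH2,DMSO-d6/D2O 7:3,293,4.30e-3,600,1.8,166,170,128,133,1.58,1.51,2.6,3.8,4.5
BGL,CH2,DMSO-d6/D2O 7:3,293,4.30e-3,900,1.8,219,249,152,153,1.45,1.33,13.6,0.6,8.3
GGM,CH,D2O,298.6,1.09e-3,600.13,1.8,456.2,453.2,416.6,425.7,2.398,2.299,0.7,2.2,4.1
GGM,CH,D2O,298.6,1.09e-3,699.87,1.8,491.1,503.8,447.4,463.6,2.267,2.148,2.6,3.6,5.3
GGM,CH,D2O,298.6,1.09e-3,600.13,1.8,491.6,470.0,450.2,444.6,2.466,2.358,4.4,1.2,4.4
GGM,CH,D2O,298.6,1.09e-3,699.87,1.8,524.5,521.5,483.9,483.6,2.346,2.203,0.6,0.1,6.1
TRI,CH2,DMSO-d6/D2O 7:3,298,3.66e-3,500,2.2,144.79,143.60,111.57,108.21,1.670,1.481,0.8,3.0,11.3
TRI,CH2,DMSO-d6/D2O 7:3,298,3.66e-3,600,2.2,167.59,169.40,117.67,118.20,1.460,1.422,1.1,0.4,2.6
TRI,CH2,DMSO-d6/D2O 7:3,298,3.66e-3,700,2.2,188.36,197.78,124.55,127.06,1.320,1.385,5.0,2.0,4.9
LNF,CH,DMSO-d6/D2O 7:3,303,1.40e-3,600,3.2,305.0,349.5,222.0,213.0,1.460,1.489,14.6,4.1,2.0
LNF,CH,DMSO-d6/D2O 7:3,303,1.40e-3,700,3.2,354.0,418.6,244.0,227.9,1.420,1.451,18.2,6.6,2.2
LNF,CH,DMSO-d6/D2O 7:3,303,1.40e-3,600,3.2,319.0,336.3,241.0,214.4,1.600,1.423,5.4,11.0,11.0
LNF,CH,DMSO-d6/D2O 7:3,303,1.40e-3,700,3.2,366.0,400.3,264.0,229.9,1.530,1.386,9.4,12.9,9.4
LNF,CH,DMSO-d6/D2O 7:3,303,1.40e-3,600,3.2,318.0,336.6,225.0,235.9,1.630,1.438,5.9,4.8,11.8
LNF,CH,DMSO-d6/D2O 7:3,303,1.40e-3,700,3.2,360.0,395.9,240.0,254.1,1.560,1.392,10.0,6.9,10.7
LNF,CH,DMSO-d6/D2O 7:3,303,1.40e-3,600,3.2,372.0,365.8,286.0,275.2,1.740,1.525,1.7,3.8,12.3
LNF,CH,DMSO-d6/D2O 7:3,303,1.40e-3,700,3.2,404.0,421.2,302.0,296.7,1.690,1.469,4.3,1.7,13.1
LNF,CH,DMSO-d6/D2O 7:3,303,1.40e-3,600,3.2,325.0,390.1,259.0,270.1,1.490,1.728,20.0,4.3,15.6
LNF,CH,DMSO-d6/D2O 7:3,303,1.40e-3,700,3.2,374.0,455.5,262.0,289.9,1.500,1.677,21.8,10.6,11.8
GCY,CH2,DMSO-d6/D2O 7:3,323,2.90e-3,400,1.8,123.5,130.7,75.00,81.59,1.430,1.458,5.9,8.8,1.9
GCY,CH2,DMSO-d6/D2O 7:3,323,2.90e-3,600,1.8,187.0,213.3,85.00,96.58,1.330,1.400,14.1,13.6,5.3
GCY,CH2,DMSO-d6/D2O 7:3,323,2.90e-3,900,1.8,314.5,370.3,110.9,109.4,1.250,1.384,17.7,1.3,10.7
GCY,CH2,DMSO-d6/D2O 7:3,343,2.30e-3,400,1.8,134.1,132.5,107.2,96.8,1.630,1.498,1.1,9.7,8.1
GCY,CH2,DMSO-d6/D2O 7:3,343,2.30e-3,600,1.8,183.8,203.6,130.1,117.3,1.510,1.405,10.8,9.9,6.9
GCY,CH2,DMSO-d6/D2O 7:3,343,2.30e-3,900,1.8,274.0,335.3,154.8,137.0,1.330,1.366,22.4,11.5,2.7
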