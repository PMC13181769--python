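# Aqueous glycine solution properties at 22 C, used to calibrate the
# Clausius-Mossotti permittivity <-> composition chain.
# Columns: x_gly (mass fraction), rho (g/cm3), eps (relative permittivity
# at 632.8 nm).
# Values computed from literature correlations: glycine apparent molar
# volume phi_V = 43.19 + 0.85 m cm3/mol (dilute-solution volumetric data,
# ~25 C); glycine molar refraction 16.4 cm3/mol (Lorentz-Lorenz); water
# density 0.99777 g/cm3 and permittivity 1.7770 at 22 C (CRC Handbook).
x_gly,rho_g_cm3,eps
0.000,0.99777,1.77700
0.025,1.00841,1.78894
0.050,1.01907,1.80101
0.075,1.02972,1.81318
0.100,1.04034,1.82543
0.125,1.05090,1.83772
0.150,1.06136,1.85003
0.175,1.07167,1.86229
0.200,1.08179,1.87446
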