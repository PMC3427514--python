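# Reference (physiological exemplar) parameter set, non-dimensional.
[parameters]
beta_B = 7.567
beta_C = 9.441
beta_Ai = 1.735
beta_Ao = 0.785
alpha_C = 2.182
alpha_A = 1.700
gamma_B = 0.701
gamma_C = 0.774
gamma_A = 0.737
gamma_N = 0.079
delta_A = 0.037
delta_N = 0.053
delta_fA = 1.955
eta_A = 0.134
eta_N = 9.136
kappa_A = 6.045
kappa_B = 1.276
kappa_C = 2.292
kappa_D = 9.284
lam = 0.422
a_1 = 1.000
a_2 = 0.500
a_4 = 1.000
a_5 = 0.461
b = 0.500
d = 1.921
mu = 0.213
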