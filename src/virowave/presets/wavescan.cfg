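# Theoretical infection-wave speed against viral clearance at fixed
# alpha/q_v (so beta_tilde is constant), for three viral diffusivities.
[model]
p = 1.87e-2
q = 4.17e-2
q_v = 1.67e-1
alpha = 580
beta = 7.00e-4
D_U = 1.88e-4
D_P = 1.50e-3
D_v = 1.00e-2
K = 1e3
movement = undirected
dimension = 1

[numerics]
tau = 0.02
delta = 0.1

[initial]
R_u = 2.6
R_v = 0.5
R_i = 0
V_0 = 2.67e4

[run]
q_v_values = 0.001 0.00316 0.01 0.0316 0.1 0.167 0.316 1.0 3.16 10.0 31.6 100.0
D_v_values = 1.0e-2 1.88e-4 1.0e-5
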