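# Burst-size scan of the maximal Poissonian control probabilities from the
# radial explicit-virus continuum systems (undirected and pressure-driven).
[model]
p = 1.87e-2
q = 4.17e-2
q_v = 8.33e-2
beta = 7.00e-4
D_U = 1.88e-4
D_P = 1.50e-3
D_v = 1.00e-2
K = 1e4
movement = undirected
dimension = 2

[numerics]
tau = 0.02
delta = 0.1
dx = 0.1
dt = 1e-3
L = 15
radial = true

[initial]
R_u = 2.6
R_v = 2.6
R_i = 0
V_0 = 7128900

[run]
horizon = 1500
record_every = 1000
alpha_values = 1000 2000 3500 7000 14000 28000 56000
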