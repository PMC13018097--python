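# Reference parameter set, one spatial dimension, undirected movement.
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
dx = 0.1
dt = 1e-3
L = 10
radial = false

[initial]
R_u = 2.6
R_v = 0.5
R_i = 0
V_0 = 2.67e4

[run]
horizon = 100
record_every = 1000
seed = 1
replicates = 5
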