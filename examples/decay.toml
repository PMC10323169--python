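# Estimate (A, k) of y(t) = A exp(-k t) from noisy synthetic observations.
base_seed = 0
n_independent_runs = 20
variant = "isres_plus"
output_dir = "decay_out"

[problem]
name = "decay_fixture"
noise_sd = 0.01
seed = 123

[es]
lam = 60
max_generations = 200
n_lin = 2
n_newt = 1
beta_lin = 2.0
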