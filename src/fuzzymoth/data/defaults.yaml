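# Default run configuration: the published experimental settings.
wwo_budget: 100000          # objective-function evaluations per training run
population: 8               # WWO wave population
n_groups: 5                 # moth groups (clusters)
fuzzifier: 2.0              # FCM fuzzifier m
u_floor: 0.1                # membership lower limit u_L
noise_level: 0.2            # masking-corruption probability
cv_folds: 5
cv_repeats: 20
step_ms: 200                # control time step
success_tol: 0.15           # relative deviation bound for a successful instruction
common_widths: [80, 46, 26]
group_widths: [26, 15, 9]
individual_widths: [9, 6, 7]
control_widths: [75, 49, 35, 32]
output_weights: [0.24, 0.2, 0.2, 0.15, 0.07, 0.07, 0.07]
seed: null
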