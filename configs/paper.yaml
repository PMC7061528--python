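# Full-budget run configuration (hours-scale on one CPU).
# Reproduces the headline landscape/kinetics analysis of the shipped
# default network at high sampling depth.
out_dir: runs/paper
seed: 1
t_max: 20000.0
n_runs: 24
burn_in: 200.0
bin_width: 5
n_bins: 96
smoothing: 1.0
delta_merge: 0.5
label_mode: nearest
min_basin_probability: 0.001
delta_core: 1.0
n_passages: 12
max_events_per_passage: 400000000
mfpt_pairs: routes
run_flux: true
run_sensitivity: true
sensitivity_t_max: 3000.0
sensitivity_n_runs: 12
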