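# Desk-scale configuration: completes in ~10 minutes on one CPU.
# Expected degradation vs paper.yaml: same seven basins at default binning,
# noisier barrier heights and first-passage estimates.
out_dir: runs/desk
seed: 1
t_max: 2500.0
n_runs: 16
burn_in: 100.0
bin_width: 5
n_bins: 96
smoothing: 1.0
delta_merge: 0.5
label_mode: nearest
min_basin_probability: 0.001
delta_core: 1.0
n_passages: 4
max_events_per_passage: 50000000
mfpt_pairs: routes
run_flux: true
run_sensitivity: false
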