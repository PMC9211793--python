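# Small end-to-end demo: a scaled-down two-hub study that runs in ~10 s.
# `ensemblefe run --config examples/demo.yaml`
out_dir: demo_out
seed: 1
bootstrap: 500
temperature: 300.0

# compound series (counts per modification subgroup; hubs L30 and L2 included)
subgroup_sizes: {"0": 1, "1": 8, "14": 6, "2": 2, "3": 3, "4": 4, "34": 3}
n_charged: 3
n_censored: 2

# end-point ensembles
protocol: 1traj
esmacs_n_replicas: 5
esmacs_n_frames: 40
esmacs_between_replica_sd: 1.0

# thermodynamic integration ensembles
ti_n_replicas: 5
ti_n_samples: 50
ti_within_sd: 0.3
ti_between_sd: 0.2
n_shared_targets: 5
common_change_bias: -1.28

# network accounting
offset_mode: reference-pair
flag_threshold: 0.5

strata: [all, charged, neutral, "1", "14", "1+14"]
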