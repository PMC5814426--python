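# Example experiment config for `eegsex run-all --config examples/experiment.yaml`
# Every key is optional; omitted keys use the scaled-down defaults.
cohort:
  n_subjects: 60
  male_fraction: 0.47
  duration_s: 120.0
  seed: 0
effect:
  beta_female_gain: 1.4
  broadband_female_gain: 1.05
n_train: 40
filter_scale: 0.1
train:
  max_runs: 2
  batch_size: 70
null:
  n_sims: 100000
  assigned_male_fraction: 0.47
dream:
  steps: 40
out_dir: scratch/experiment_out
seed: 1
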