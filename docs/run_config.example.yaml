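# Example pipeline configuration for `uwbfall run --config <file>`.
# Top-level keys map to RunConfig fields; `preprocess` and `model` sections
# override PreprocessConfig / ModelConfig defaults.

seed: 1
out_dir: run_output
environment: lab          # lab (empty room) or lounge (heavily furnished)
n_bins: 128               # fast-time bins per frame; full room extent kept
n_subjects: 2
samples_per_subject_per_activity: 6
noise_sigma: 0.02         # echo noise, units of the torso peak amplitude

preprocess:
  aug_step: 2             # window-translation step, bins (~9 cm here)
  n_aug: 5

model:
  conv_filters: [16, 16]
  convlstm_hidden: 8
  max_epochs: 30
  batch_size: 100
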