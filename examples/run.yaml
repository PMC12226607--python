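# Full multi-step protocol on a manifest dataset (see `replayseg make-data`).
manifest: data/manifest.csv
steps:                 # class ids introduced at each incremental step
  - [1, 2, 3]
  - [4, 5]
train:
  epochs_initial: 24
  epochs_per_step: 16
  batch_size: 16
  lr: 0.01
  diffusion_steps: 60
  diffusion_epochs: 50
  replay_n: 64
  replay_ratio: 0.5
  tau: 0.1
  confidence_threshold: 0.7
  use_kd: true
  use_replay: true
  use_cl: true
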