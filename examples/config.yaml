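# Desk-scale run: synthetic complementary cohort, lite CT backbone.
# Any omitted key takes its documented default; unknown keys are rejected.
seed: 0
outdir: runs/demo

synthetic:
  n_samples: 300
  modality_signal: complementary   # pb_only | ct_only | complementary | redundant
  volume_shape: [16, 32, 32]

gnn:
  n_layers: 4
  hidden_dim: 32
  pool_ratio: 0.5
  graph_threshold: 0.3

cnn:
  backbone: resnet_lite_3d
  input_shape: [16, 32, 32]
  epochs: 25
  hu_window: [-1000.0, 400.0]

fusion:
  rank: 4
  n_tokens: 8
  d_model: 32
  heads: 4

train:
  split_mode: ratio_3_1_1          # or kfold (5 folds)
  pb_epochs: 120
  head_epochs: 60
  joint_epochs: 6
  shortlist_size: 4
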