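# 62-channel, 5-class preset (session-wise trial split protocol).
# This dataset style gets the 0.3-75 Hz zero-phase band-pass after the
# 200 Hz resample.
model:
  n_channels: 62
  n_patches: 4
  patch_size: 200
  n_classes: 5
  embedding:
    embed_dim: 32
    patch_size: 200
    conv_kernel: 7
    gn_groups: 4
  ssd:
    d_state: 16
    n_heads: 4
    head_dim: 16
    expand: 2
  backbone:
    depth: 4
    bidirectional: true
    residual: true
  head:
    n_classes: 5
    n_attn_heads: 4
    mlp_hidden: [256, 64]
    dropout: [0.5, 0.3]
    smoothing: 0.1
preprocess:
  target_sfreq: 200.0
  apply_bandpass: true
  band: [0.3, 75.0]
  patch_size: 200
split:
  by: trial
  n_train: 5
  n_val: 5
train:
  lr: 1.0e-4
  weight_decay: 1.0e-4
  batch_size: 32
  epochs: 200
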