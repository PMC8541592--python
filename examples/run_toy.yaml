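# Full pipeline configuration for the desk-scale pair generated from
# toy_t3.yaml (run `countda generate examples/toy_t3.yaml data/toy` first).
seed: 0
out_dir: ../runs/toy
data:
  source: ../data/toy/source
  target: ../data/toy/target
model:
  backbone: small_cnn
  feature_dim: 128
  image_size: 64
pretrain:
  lr: 2.0e-3
  batch_size: 32
  max_epochs: 80
  patience: 10
adapt:
  d_lr: 3.0e-4
  g_lr: 2.0e-5
  batch_size: 32
  max_epochs: 45
  lam: 0.1
finetune:
  lr: 2.0e-3
  batch_size: 16
  max_epochs: 200
  k: 50
monitor:
  mode: both
  patience: 10
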