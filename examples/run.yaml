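# Desk-scale end-to-end run: 54 phantoms at 48^3 / 3 mm, 3-model ensemble.
n_plans: 54
seed: 1
prescription_Gy: 45.0
grid: 48
spacing: 3.0
n_models: 3
out_dir: runs/demo
network:
  in_channels: 16
  levels: 1
  block_layers: 1
  growth: 8
  dilations: [1, 2]
train:
  patch_size: 24
  patches_per_epoch: 48
  batch_size: 4
  max_epochs: 10
  val_patch_size: 32
patch:
  size: 24
  stride: 16
thresholds:
  theta_mean_Gy: 2.0
  theta_max_Gy: 3.0
equivalence_bound_Gy: 1.0
alpha: 0.05
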