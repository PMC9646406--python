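# Miniature configuration for CPU-scale runs of the full pipeline.
phantom:
  shape: [48, 48, 48]
  n_stable_lesions: 2
  n_new_lesions: 2
  lesion_radius_range: [2.0, 4.0]
network:
  n_levels: 3
  base_width: 8
  n_deep_supervision: 2
  patch_size: [32, 32, 32]
train:
  steps: 300
  batch_size: 2
  lr: 0.003
loss:
  dice_mode: classwise
  gt_downsample_mode: maxpool
augment:
  patch_size: [32, 32, 32]
  p_affine: 0.0
  flip_p: [0.5, 0.5, 0.5]
  p_intensity: 0.05
inference:
  window: [32, 32, 32]
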