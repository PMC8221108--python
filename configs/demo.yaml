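# Small synthetic cohort demonstrating the full pipeline:
# 2x2x2 design (sex x condition x side) in the DRG, 3 samples per group,
# with a male-only ipsilateral recruitment effect (3x cell density) and an
# injury-associated oblate (flattened, M1-like) shape shift.
out_dir: runs/demo
seed: 1
n_samples_per_group: 3
tissues: [DRG]
scene:
  stack_shape: [64, 192, 192]     # (z, y, x) voxels
  voxel_size: [1.0, 0.5, 0.5]     # µm per voxel, (z, y, x)
  n_cells: 12                     # expected cells per stack (Poisson)
  cell_intensity: 150.0
  background_intensity: 20.0
  noise_sd: 4.0
effects:
  male/SNI/ipsilateral/DRG: {density_multiplier: 3.0, shape_mode: oblate}
  male/SNI/contralateral/DRG: {density_multiplier: 1.0, shape_mode: oblate}
  female/SNI/ipsilateral/DRG: {density_multiplier: 1.0, shape_mode: oblate}
  female/SNI/contralateral/DRG: {density_multiplier: 1.0, shape_mode: oblate}
segmentation:
  background_sigma: 10.0          # µm
  cell_threshold: 50.0
  min_voxels: 50
  max_voxels: 10000
  connectivity: 3                 # 26-neighborhood
  tissue_threshold: 10.0
histogram_bins: 20
alpha: 0.05
phenotype_margin: 0.05
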