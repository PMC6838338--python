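# Example full-pipeline configuration (small sizes for a quick run).
# Omit `mri.matrix` / `group_sizes` to simulate at the full acquisition
# matrix (192x192) and study group sizes (NH 11 / NE 11 / NE+AO 8).
seed: 1
outdir: questmri-out
stages: [simulate, r1map, quest, abr, histo]
alpha: 0.05
contrast_method: scheffe
mri:
  matrix: [64, 64]
  noise_sigma: 0.03
  jitter_sigma: 0.5
  coil_kind: low-order-polynomial
  coil_amplitude_range: [0.8, 1.2]
  group_sizes: {NH: 4, NE: 4, NE+AO: 4}
abr:
  n_subjects: 6
  level_step: 5
histology:
  bin_width_pct: 5.0
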