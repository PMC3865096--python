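# Cohort analysis configuration.
#
# Study design: four arms (control, MK1775, Gem, Combo), 4 mice x 2 flank
# tumors per arm, imaging at baseline, 24 h after each treatment (days 1, 3,
# 8, 10 -> imaging days 2, 4, 9, 11) and on day 14; b = 50/500/1000/2000
# s/mm^2, 136 um in-plane / 1.5 mm slices.  The phantom grid and tumor radius
# are scaled down from the full 128x128 acquisition so the whole cohort
# simulates and fits in minutes on one CPU; the statistical design is
# unchanged.  Effect profiles are qualitative response mimics (documented in
# docs/methods.md), not measured values.
seed: 1
phantom:
  grid_shape: [64, 64, 10]
  voxel_size: [0.136, 0.136, 1.5]
  tumor_radius: 2.2      # mm
  adc_mean: 1.1e-3       # mm^2/s
  adc_sd: 1.5e-4
  s0_mean: 1000.0
  snr: 25.0
  bvalues: [50.0, 500.0, 1000.0, 2000.0]
  correlation_length: 0.5
  noise_model: rician
figures: true
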