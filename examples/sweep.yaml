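# Example campaign: kernel-size ladder and localization accuracies on a
# 512x512 filament phantom, emitter counts spanning three decades (1/100 of
# the 2048x2048 full-frame counts, so the whole sweep runs in minutes).
# Run with:  smlmfid sweep examples/sweep.yaml --seed 11 --out results/sweep
reference:
  phantom: filament
  width: 512
  height: 512
  pixel_size: 6.4
  n_filaments: 5
  thickness: 50.0
  seed: 7
n_grid: [500, 5000, 50000, 500000]
kappa_grid: [6.4, 25.0]
d_grid: [6.4, 32.0, 57.6, 108.8, 211.2]
kernel: square
n_f: 1000
k_rings: 32
n_replicates: 3
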