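# smlm-fidelity

Simulation and scoring of reconstruction fidelity in single-molecule
localization microscopy (STORM/PALM).

Localization microscopy reconstructs an extended biological structure —
membranes, chromatin domains, cytoskeletal filaments — from a cloud of
localized emitter positions. How faithful that reconstruction is depends on
three knobs: the density of registered emitters *N*, the localization
accuracy κ (the standard deviation of the position error, in nm), and the
size *d* of the kernel (square or Gaussian) deposited at each localized
position when the image is rendered. This package lets you treat image
quality as the function IQ(N, κ, d): it simulates the detection process on
top of a known ground-truth density map and quantifies the agreement between
reconstruction and truth with four complementary measures. It is aimed at
microscopists and methods developers who want to know how many localizations
a given structure needs, and at what kernel size to render them.

## Model

A reference image defines a relative emitter density ρ(x, y) ∈ [0, 1].
Emitters are drawn by rejection sampling (accept a uniform candidate (x, y)
when a uniform p ≤ ρ(x, y)), then perturbed by independent Gaussian errors
δx, δy ~ N(0, κ²). The reconstruction I_rec accumulates, at each localized
position, either a d × d nm square of amplitude 1 or an isotropic Gaussian
(σ = d/2 by default; σ = d selectable).

Fidelity of I_rec against the reference I₀ is scored by:

- **Q_pearson** — the Pearson correlation coefficient of the pixel arrays;
- **Q_binarized** = 1 − Σ|B₀ − B_rec| / ΣB₀, the overlap of the two
  independently Otsu-binarized images (can go negative when false-positive
  area exceeds the reference foreground; returned unclamped);
- **Q_L2** — the squared L2 distance between the mean-centered, unit-norm
  images; identically 2 (1 − Q_pearson), which the tests exploit as a
  cross-check;
- **Q_freq(f)** — a frequency-resolved phase-agreement spectrum: with
  Î(f_x, f_y) = e^{iη} A, each radial ring of width δf = f_max/k reports
  the ring mean of cos(η₀ − η_rec). It is 1 at frequencies reconstructed
  perfectly and 0 where the images are uncorrelated — a ground-truth
  analogue of Fourier ring correlation.

Local sampling is quantified by Voronoi tessellation of the localizations
(cells clipped to the image): δr = √(area/π) is the local sampling interval,
and the limiting precision combines sampling and localization error as
δl = √(δr² + δg²), with δg taken equal to κ.

## Worked example

```python
import smlm_fidelity as sf

ref = sf.make_filament_phantom(512, 512, 6.4, n_filaments=5, thickness=50.0, seed=7)
emitters = sf.sample_emitters(ref, n_max=50_000, kappa=25.0, seed=1)
rec = sf.render(emitters, ref, kernel="square", d=32.0)

print(sf.emitter_density_per_um2(emitters.n, ref.width, ref.height, ref.pixel_size))
print(sf.q_pearson(ref.values, rec.values),
      sf.q_l2(ref.values, rec.values),
      sf.q_binarized(ref.values, rec.values))

fs = sf.q_freq(ref.values, rec.values, k=32, pixel_size=ref.pixel_size)
radii = sf.voronoi_radii(emitters, ref)
stats = sf.summarize_sampling(radii, delta_g=emitters.kappa)
print(stats.summary["p50"], stats.limiting_period_median)
```

prints (rounded):

```
density per um2: 4656.6
q_pearson  = 0.841
q_l2       = 0.318
q_binarized= 0.225
q_freq ring 1: 0.907   ring 8: 0.022   ring 32: 0.012
median delta_r = 3.2 nm; p95 = 8.0
limiting period (median delta_l): 50.4 nm
```

Reading: at ~4 700 emitters/µm² with κ = 25 nm and 32 nm squares, the
reconstruction correlates well with the truth overall (Q_pearson 0.84,
Q_L2 = 2(1 − 0.84) ≈ 0.32), but the spectrum shows the large-scale structure
is recovered (ring 1 near 0.9) while fine detail is not (rings ≥ 8 near 0).
That matches the Voronoi analysis: the median limiting precision δl ≈ 25 nm
implies a limiting period of ~50 nm, so nothing much finer than ~50 nm
periods can be recovered — and the binarized overlap stays modest because
isolated false-positive deposits inflate the reconstructed foreground.

The same pipeline is scriptable from the shell:

```
smlmfid phantom ref.tif --kind filament --seed 7
smlmfid sample ref.tif locs.csv --n 50000 --kappa 25 --seed 1
smlmfid render locs.csv rec.tif --d 32
smlmfid measure ref.tif rec.tif
smlmfid sweep examples/sweep.yaml --seed 11 --out results/sweep
```

The `sweep` subcommand runs the full campaign IQ(N, κ, d) — one emitter set
per (κ, d) cell, measures recorded at every emitter count in the grid —
and writes a flat `records.csv` plus the per-frame spectra. From the records,
`sf.optimal_d(records, n, kappa)` reports the kernel size that maximizes
Q_pearson and whether that optimum is interior to the swept range: at sparse
sampling large kernels win, at dense sampling the optimum moves to smaller
kernels, and the two regimes cross.

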