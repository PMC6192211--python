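# Methods

## Model and scope

The package treats single-molecule localization microscopy as a two-stage
stochastic sampling of a continuous structure. A reference image supplies a
relative labeling density ρ(x, y) normalized to [0, 1]; nothing else about
the imaging physics enters. Detection is modeled as rejection sampling from
ρ followed by an isotropic Gaussian localization error of standard deviation
κ per axis. κ is a single free parameter per run: it absorbs photon count,
camera noise and pixelation, wavelength and the fitting algorithm, whose
individual influence on precision is well characterized elsewhere and is
deliberately not re-modeled here. There is no blinking kinetics, no repeated
activation of the same fluorophore and no multi-emitter fitting artifact in
the model; each accepted emitter is an independent draw.

Coordinates are continuous and in nm, origin at the top-left pixel corner,
x rightward, y downward; the center of pixel (i, j) is at
((j + 0.5)·p, (i + 0.5)·p) for pixel size p. This one convention is used by
the sampler, the renderer and the tessellation alike.

## Fidelity measures

Q_pearson, Q_binarized and Q_L2 are standard; the only non-obvious choices:

- Otsu thresholds are computed per image on a 256-bin histogram spanning
  that image's own [min, max]; the two images are binarized independently.
  Q_binarized is returned unclamped — values below 0 mean the false-positive
  area exceeds the reference foreground, which is real information at very
  low emitter counts.
- Q_L2 is computed from the mean-centered, L2-normalized arrays, so it
  satisfies Q_L2 = 2 (1 − Q_pearson) exactly. The test suite asserts this
  identity to 1e-10; it is the main guard against an implementation drift
  between the two scalar measures.

The frequency measure decomposes the 2-D DFTs of both images into phase and
amplitude, Î = e^{iη} A, and averages the *phase agreement* over radial
rings: ring value = mean of cos(η₀ − η_rec) over the frequency samples in
]f, f + δf], with δf = f_max/k and f_max the Nyquist frequency of the pixel
grid. Written as a bare product of phase factors the quantity e^{iη₀}
(e^{iη_rec})* has the stated endpoints — 1 when every phase agrees, 0 in
expectation when phases are unrelated — only after taking the real part and
normalizing by the ring population, so that is what is implemented. A
literal product of the two phase *angles* would be neither bounded nor
dimensionally meaningful, and is not offered. Implementation details:

- the DC sample is excluded (its phase is identically 0 for non-negative
  images and would bias the first ring);
- samples with exactly zero amplitude in either image have no defined phase
  and are dropped; a ring left empty is reported as NaN, never as 0;
- corner samples beyond f_max are outside every ring;
- cos(η₀ − η_rec) is evaluated as Re(F₀ F_rec*)/(A₀ A_rec), avoiding angle
  unwrapping;
- no window is applied by default; a Tukey (α = 0.25) taper is available
  for strongly non-periodic real images, where border discontinuities leak
  power across rings.

## Rendering

Square kernel: an axis-aligned d × d nm square of amplitude 1; a pixel
belongs to it when its center lies inside, with centers exactly on the low
edge included and on the high edge excluded (deterministic tie-break). When
d is an integer multiple of the pixel size every interior emitter covers
exactly (d/p)² pixels regardless of sub-pixel position. Gaussian kernel:
peak amplitude 1, σ = d/2 by default (σ = d selectable via a flag recorded
in all outputs; the comparison between square and Gaussian rendering uses
2σ = d, i.e. matching the square side to the central ±σ width). The Gaussian
is evaluated on the |Δx|, |Δy| ≤ 3σ bounding box and is zero outside;
the truncation costs ~0.5% of the mass, inside the 1% tolerance the
mass-conservation test allows. Kernels of constant peak amplitude rather
than unit mass are deliberate: all four measures are scale-invariant, and at
fixed d the two conventions differ only by a global factor.

Per-emitter amplitude 1 is exact in float64, and Gaussian kernel samples are
quantized to integer multiples of 2⁻²⁶ (relative error ≈ 1.5e-8) before
deposit. Accumulation is therefore *exact and order-independent*, which
gives two useful guarantees: the last frame of an incremental rendering is
bit-identical to a one-shot render of the same set, and a sweep may deposit
emitters in any order without changing any measure. The square kernel also
gets an integral-image fast path (four scatter-adds plus a double cumsum per
batch), cross-checked in the tests against the naive per-emitter
rasterization for bit-equality. Exactness holds while any single pixel
accumulates fewer than ~2²⁷ emitters, far beyond any realistic density.

Emitters pushed outside the image by the localization error are kept in the
set; rendering clips their footprint (possibly to nothing) but they still
count as rendered. A kernel smaller than half a pixel triggers a warning and
degrades to a single-pixel deposit.

## Sampling density and limiting precision

The Voronoi tessellation of the localized positions is computed after
mirroring the point set across the four image edges; each original point's
cell in the augmented diagram is then finite and coincides exactly with its
cell clipped to the rectangle, so cell areas tile the image area by
construction (asserted to 1e-6 relative). A single point inside the bounds
degenerates to owning the whole rectangle. Exactly duplicated positions are
separated by a deterministic golden-angle spiral of magnitude 1e-6 length
units before tessellating.

δr = √(area/π) is the local sampling interval; δl = √(δr² + δg²) the
limiting precision. δg is identified with the run's κ — the quadrature
structure (a sampling term combined with a localization term) admits no
other reading, but it is an identification, not a derivation. Because
"limiting frequency δl/2" can be read as a length or as a frequency, the
summary reports both the limiting *period* 2·δl (nm) and the Nyquist-style
limiting *frequency* 1/(2·δl) (cycles/nm), each at the median and at the
95th percentile of δl. The 95th percentile is included because the maximal
recoverable spatial frequency is set by the worst-sampled region, not the
average one; a regression test verifies on a nucleus phantom that the
p95-based prediction lands closer to the measured phase-agreement cutoff
than the mean-based one. δr is computed from localized (not true) positions:
they are what an experimenter has.

## Synthetic phantoms

Two generator classes cover the two structure archetypes the measures react
to differently:

- *Filament phantom*: quasi-parallel wavy ridges of given thickness
  (parabolic cross-section) spanning the image — repetitive structure
  distributed fairly uniformly, one foreground component per filament. With
  the defaults (512², 6.4 nm pixels, 5 filaments, 50 nm thickness) the Otsu
  foreground fraction is ~7%.
- *Nucleus phantom*: a few super-Gaussian blobs (peak density 0.95, flat
  core) over a sparse uniform background of 0.05 — few dense regions
  occupying a small area fraction, with most of the field sparsely labeled.

Both are deterministic for a fixed seed. They emulate the *geometry classes*
(repetitive-uniform vs. concentrated-sparse) and the resulting sampling
statistics; they do not emulate electron-microscopy texture, staining
nonlinearity or instrument noise in the reference. Tests passing on phantoms
therefore validate the machinery and the direction of the density/κ/d
effects, not numeric values for any particular specimen. How physical image
intensity maps to labeling density in real references is unknown in general;
loading assumes a linear min–max mapping to [0, 1].

## Study conditions and problem sizes

The sweep protocol samples one emitter set of size max(n_grid) per
(κ, d, replicate) cell and reads all four measures off the running canvas at
each count in n_grid — smaller counts are intermediate frames of the same
realization, not independent runs; three replicate seeds (default) quantify
Monte-Carlo spread. The shipped example grid uses the kernel ladder
d ∈ {6.4, 32, 57.6, 108.8, 211.2} nm on a 6.4 nm pixel grid, κ ∈ {6.4, 25} nm,
and emitter counts 5·10² – 5·10⁵ on a 512² phantom — the same densities
(291–291 000 µm⁻²) as a 2048² frame at 1/100 the counts, chosen so a full
campaign completes in minutes on one core. The qualitative phenomena
(crossing of the Q_pearson-vs-d curves, interior optimum moving to smaller d
with density, kernel-independence of the spectrum below aliasing with a
strong aliasing depression for the largest kernel, poorer κ requiring more
emitters) are all reproduced at this scale; the aliasing comparison is made
on the lowest third of the frequency axis, where the reference spectrum has
meaningful power.

## Numerical and API choices

- Rejection sampling evaluates ρ at the containing pixel by default
  (bilinear interpolation is optional); candidates are continuous-uniform
  over the rectangle. Draw order is fixed — candidate batches first, then
  one block of 2n Gaussian offsets — so runs are bit-reproducible per seed.
- Sweep cell seeds derive from the master seed through `SeedSequence`
  hashing of (seed, replicate, κ-index, d-index): cells are statistically
  independent but fully reproducible.
- `optimal_d` averages replicates, breaks ties toward smaller d (finer
  rendering preferred) and flags whether the argmax is interior to the grid.
- Degenerate inputs fail loudly and early: constant images, all-zero
  densities, empty foregrounds and ill-posed tessellations raise typed
  errors rather than returning NaN.

## Known limitations

- No blinking/reactivation model: emitter counts are counts of *independent*
  localizations, so densities here are optimistic relative to experiments
  with heavy re-counting.
- A single κ per run; mixed-precision localization tables are out of scope.
- Q_freq compares against a known reference; it is not the split-set FRC
  resolution estimate used when no ground truth exists.
- The phantoms are 2-D; no axial dimension anywhere.
- Voronoi statistics on >10⁵ points are memory- and time-hungry (the mirror
  construction tessellates 5n points); subsample localizations if that
  matters.
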