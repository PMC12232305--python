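# Methods

This note records the models implemented in `flimforge`, the parameter
choices that matter, and the limits of what the synthetic data can show.

## Time base

All simulation defaults use a uniform grid of 256 bins of 0.0977 ns
(`axes.TimeAxis`), a 25.01 ns record matching a 40 MHz pulsed laser.
Bin *k* is anchored at *k*·Δ (0-based); decay models are evaluated at
these anchors, while the phasor transform evaluates its Fourier kernels
at bin centers (*k*+½)·Δ. The half-bin offset between the two
conventions is deliberate: it cancels the leading O(Δ) discretization
bias so the discrete phasor of a sampled exponential agrees with the
continuous closed form 1/(1+iωτ) to O(Δ²) (verified to <0.5 % in the
tests).

## IRF model

The instrument response is a skew-normal primary peak plus an optional
Gaussian secondary peak modelling detector after-pulsing:

    IRF(t) = (2/σ)·φ(z)·Φ(λz) + a·N(t; μ′, σ′),   z = (t−μ)/σ

normalised to a maximum of 1. σ is always set from the target FWHM via
σ = FWHM / (2√(2 ln 2)), including when λ ≠ 0; a strong skew therefore
narrows the realized width below the nominal target (a λ = 5 draw
measures roughly half its target FWHM). This is accepted: the library is
meant to span a broad range of temporal resolutions, not to hit exact
widths, and `measure_fwhm` (half-maximum crossings located by linear
interpolation between bins) reports the realized value of any curve.

Library sampling defaults (`IRFLibraryConfig`):

| parameter | default | rationale |
|---|---|---|
| FWHM classes | 220, 400, 800 ps | narrow / standard / degraded detectors |
| skew λ | U[1, 5] | slight-to-strong positive asymmetry from detector transit delays |
| secondary peak | present with p = 0.5 | after-pulsing is common but not universal |
| secondary amplitude a | U[0, 0.2] | small relative to the main peak |
| secondary delay μ′−μ | U[0.5, 2] ns | typical after-pulse lag |
| secondary width σ′ | U[0.5σ, 1.5σ] | comparable to the primary width |
| peak bin after shift | integer U{12, …, 58} | emulates laser jitter / setup variation across a database of instruments |

Peak shifting is an integer-bin roll with zero fill of vacated bins — no
sub-bin interpolation, preserving photon-histogram semantics. The
"12th to 58th bin" span is read as inclusive 0-based indices. Library
generation is a pure function of (config, seed).

## FLIM image simulation

Each image composes four steps:

1. **Structure channels.** 1–4 nonnegative intensity images, produced by
   thresholding fractal Perlin noise (3 octaves, lacunarity 2,
   persistence 0.5, base features ≈ 1/8 of the frame) at its 80th
   percentile. This guarantees ≥5 % structure coverage and yields smooth
   blob/filament shapes. These are procedural stand-ins for single-cell
   micrographs: they reproduce spatial smoothness and channel overlap
   but not real organelle morphology.
2. **Lifetimes.** Per channel, a base lifetime ~ U[0.1, 10] ns and a
   variability half-range ~ U[0.2, 2] ns; per-pixel lifetimes are
   base + U[−v, +v], clipped back to [0.1, 10] ns. Uniform additive
   jitter was chosen over Gaussian or spatially correlated jitter as the
   simplest model of pixel-level heterogeneity; nothing downstream
   depends on the jitter law.
3. **Photon targets.** The summed channel intensities are mapped
   affinely onto the regime's photon range — 100–2500 photons/pixel
   (high) or 10–100 (low) — and rounded; background pixels get 0. A
   constant composite degenerates to the range midpoint. Targets are
   pre-noise means: realized totals fluctuate around them by Poisson
   statistics.
4. **Decays.** Per non-background pixel, Σᵢ aᵢ·exp(−t/τᵢ) with fractions
   aᵢ from per-channel Perlin fields (shifted positive, normalised to
   sum to 1 at every pixel), convolved causally with the IRF (discrete
   linear convolution truncated to the window; a delta IRF is the exact
   identity; no circular wrap, since photons cannot precede excitation
   within the record), scaled so the noiseless bin sum equals the photon
   target, then Poisson-sampled per bin.

All channels contribute Perlin-weighted fractions at every
non-background pixel; contributions are not gated by per-channel
intensity support. The per-pixel ground truth is the amplitude-weighted
mean Σᵢ aᵢτᵢ (an intensity-weighted alternative, Σ aᵢτᵢ²/Σ aᵢτᵢ, is
available via the `weighting` switch); it always lies in the convex hull
of the contributing lifetimes. Background pixels carry all-zero decays
and ground truth 0 and are excluded from all evaluation.

Photon thinning (`subsample_photons`) draws exactly the per-pixel target
without replacement from the existing histogram (multivariate
hypergeometric), so totals are exact and bin proportions are preserved
in expectation.

### Fixtures

- **Flower**: a 16×16 rose-curve mask; the 4 central pixels at exactly
  1 ns, petals ~ U[4, 6] ns, 20 photons/pixel — a stress test for
  spatial smearing by binned estimators.
- **Uniform/single-pixel pairs**: 28×28 frames with one shared
  mono-exponential lifetime ~ U[0.4, 6] ns at 100 photons/pixel, plus a
  copy zeroed everywhere except pixel (10, 10) (0-based row, col), whose
  decay is bitwise identical — isolates the value of spatial context.
- **Two-region frames**: vertical/horizontal/diagonal splits at 1 ns and
  4 ns, every pixel at the same photon target, on a coarse 64-bin,
  0.3908 ns axis (same 25 ns span). These are the "easy" training task
  for learning-behaviour tests; 64 time bins keep CPU training cheap
  while fully resolving a 1 ns vs 4 ns contrast.

## Phasor baseline

g and s are photon-weighted cosine/sine moments at ω = 2π·0.04 rad/ns
(first harmonic of 40 MHz; the harmonic is configurable). Phase and
modulation lifetimes follow the standard identities; the reported value
is their average. Calibration maps a measured reference phasor onto the
theoretical semicircle point of a known reference lifetime (default
4 ns) by a complex rotation+scale; it is exact on the reference itself.
3×3 binning sums decay histograms over the neighborhood before the
transform (not averaging of lifetimes).

Numerical policy for noisy pixels: radius excursions beyond the
universal circle are clipped to it; pixels with g ≤ 0 (phase beyond the
quarter period, only reachable through noise) have no phase lifetime —
in the default robust map they fall back to the modulation estimate and
are clamped nonnegative, while the scalar API flags them with NaN.
Zero-count pixels are masked as background.

## Lifetime-regression network

Architecture: time is encoded into the channel dimension, so a
(T, H, W) stack enters a 2D network as T channels. The backbone is a
stem CBL (3×3 conv + batch norm + SiLU) followed by stride-2 CBL
downsampling stages each with a C3 cross-stage block (bottleneck
residuals), ending in an SPPF module (three chained stride-1 5×5 max
pools, concatenated). The neck upsamples (nearest, 2×) and concatenates
the matching backbone feature at each scale, U-Net style; the head is a
1×1 convolution with ReLU, so outputs are nonnegative and keep the input
spatial resolution. `stage_channels` × `width_multiplier` set the
widths; the downsampling factor is 2^(stages−1) and inputs must be
divisible by it (pad or crop first).

The network, backpropagation and AdamW are implemented directly in
numpy. End-to-end gradients are verified against central finite
differences in the test suite. He-normal initialisation; batch-norm
momentum 0.1, eps 1e-5; inference uses running statistics, making
prediction deterministic.

Training: per-pixel max-normalised decays as input (so absolute photon
count is not a feature — only curve shape and spatial context), MSE
loss against the ground-truth map, AdamW with learning rate 0.01 and
weight decay 1e-8, batch size 10, 80/20 train/validation split, early
stopping when validation MSE fails to improve for `patience` (default
20) consecutive epochs, best-validation weights restored. Background
pixels are included in the loss with target 0 by default
(`background_in_loss=False` restricts the loss to structure pixels).

Desk scale: the tested configuration (width 0.25, three stages →
channels [8, 16, 32], ≈28 k parameters, 64 input bins) trains on 64
two-region 28×28 images to < 0.05 ns² validation MSE in 50 epochs in
about half a minute on one CPU core. The full-scale configuration
(256 input channels, YOLOv5-s widths) is expressible but not exercised.

What passing these tests shows — and does not: the architecture can
learn per-pixel lifetimes from decay shape and exploits spatial context
(masking all neighbours of a pixel measurably degrades its prediction,
while the per-pixel phasor baseline is exactly indifferent). It does not
show generalisation to real microscopy data, which would require the
full-scale training corpus and experimental IRFs.

## Evaluation

MSE is computed only over non-background ground-truth pixels, making
scores comparable between methods that do and do not smear signal into
the background. Benchmark sweeps hold the scene (structure, lifetimes,
fractions — hence the ground truth) fixed across conditions and
re-simulate only the photon counts / IRF / noise, so condition effects
are not confounded by scene variation. All sweeps are pure functions of
(config, seed).

## IO and degenerate inputs

HDF5 is canonical (counts + bin width + bin count + IRF id); TIFF
carries no temporal metadata, so the bin width must be declared on
import — never defaulted. Temporal rebinning conserves per-pixel photon
totals exactly: integer ratios sum adjacent bins; non-integer ratios
distribute counts by fractional bin overlap and round by per-pixel
largest remainder. Bin counts outside 50–1000 trigger a warning, not an
error. Spatial squaring zero-pads symmetrically (or center-crops) and
returns a geometry record to map results back. Intensity masks use an
inclusive ≥ threshold. All-zero decays normalise to all-zero; empty
masks, zero-photon targets, constant composites and vendor binary
formats produce explicit, named behaviour rather than silent defaults.

## Known limitations

- Procedural structure channels approximate cellular layouts only
  statistically; no real micrographs are bundled or downloaded.
- The IRF model omits detector dark counts, pile-up and deconvolution.
- Realized IRF FWHM undershoots the nominal target at strong skew (see
  above).
- The phasor baseline applies reference calibration only; no IRF
  deconvolution.
- Checkerboard-prone deconvolution layers are avoided by using nearest
  upsampling, but no explicit anti-checkerboard regularisation exists.
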