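# Methods

## Forward model

The package models heat diffusion in a stack of N homogeneous layers,
`z ∈ [0, z_N]` with z increasing downward from the imaged surface.
Perfusion and metabolic heating are neglected: the regime of interest is
rapid, externally driven heating, where conduction dominates.  (A perfusion
term would enter the axial wavenumber as an additive real rate; the code has
no hook for it and none is tested.)  Temperatures are rises over the
far-field baseline, which makes the vanishing-at-infinite-radius boundary
condition exact and lets a spatially uniform ambient enter only through the
k = 0 bin of the boundary term.

For a drive `q_DC + q_AC cos(ωt)` the complex amplitude per transverse
Fourier bin satisfies `T'' − μ²T = −Q/κ` with
`μ = sqrt(k² + jω/D)`, `Re μ ≥ 0` (principal square root), so `e^{−μz}` is
the direction decaying with depth.  The DC problem is the same code path at
ω = 0.  Interface continuity of temperature and conductive flux gives a 2×2
transfer matrix per interface; convective (Robin) closures at both faces
and the particular solution of the source (a sheet at `z_s`, or trapezoid
quadrature over depth nodes for volumetric sources, Heaviside convention
H(0) = 0) complete a closed-form expression for the surface spectrum, split
into a source-driven and a boundary-driven part.

### Numerical choices

- **Overflow control.**  Raw transfer-matrix entries contain `e^{+μz}`
  factors that overflow double precision near `|μ|z ≈ 700` — routinely
  exceeded at camera-scale spatial frequencies.  Every matrix is stored as
  a bounded matrix times a real log-scale; products are renormalised per
  bin; the final surface-response ratio cancels the scales, and the
  leftover `e^{−Σscale}` factor on the source term underflows to zero
  exactly where the physical response is negligible.
- **Degenerate DC bin.**  At `k = 0, ω = 0` the printed closure
  coefficients have a removable 0·∞ form.  The bin is evaluated at
  `k = 10⁻⁷/z_N` instead; the relative error of this regularisation is
  O(10⁻¹⁴), though the coefficient parameterisation itself loses a few
  digits to cancellation there (verified ≤ 10⁻⁸ relative against a
  closed-form DC solution).
- **Singular parameterisation.**  The top-face coefficient divides by
  `κ₁μ₁ − h_up`, which can vanish on a measure-zero ring of bins.  Affected
  bins are nudged by one part in 10⁹ in ω (in k² for the DC problem) and
  the computation retried once before raising an error naming the bins.
- **Transforms.**  Forward kernel `e^{+j k·r}` with the `dx dy` measure,
  `1/(2π)²` and `dk` on the inverse, so spectra carry physical units and
  convolution with the TPSF reproduces the surface field bit-for-bit.
- **Finite grid.**  The model assumes the field vanishes at infinite
  radius.  `surface_field` warns when the border magnitude exceeds 1% of
  the peak; DC fields spread over several centimetres under weak convection
  and need correspondingly wide grids.

## Lock-in processing

Demodulation takes a single temporal DFT bin over the largest whole number
of modulation cycles (rectangular window; the simulated protocol starts
after transients, so integer-cycle truncation controls leakage), after
per-pixel mean removal, scaled so a cosine of amplitude a returns
magnitude a.  **Phase convention:** a pixel trace
`offset + a cos(ωt + φ)` demodulates to `a e^{+jφ}` — the same complex
amplitude the forward model predicts, so simulate → demodulate is an exact
round trip including phase, which the phase-based depth estimator relies
on.  Phases are reported in (−π, π].

Per-pixel SNR is the signal-bin power over the *mean* power of the
remaining bins, excluding DC and ±1 bin around every integer harmonic of
the demodulation frequency (the squared-voltage drive makes harmonics
signal, not noise).  With mean per-bin noise the SNR of a fixed scene grows
linearly with the number of recorded cycles (coherent gain); a summed-noise
convention would be record-length invariant by Parseval and could not show
that gain.

Hotspot FWHM interpolates the two half-maximum crossings linearly along an
axis-aligned line through a detected peak; transverse resolution is the
mean hotspot FWHM minus the physical source width (1.7 mm for the phantom
resistors), clipped at zero; visibility is (max − min)/mean along a line
across neighbouring sources.  Hotspot detection takes local maxima 6 dB
above a noise floor (default: the image median) with ≥ 3 px separation; the
CLI pipeline raises that floor to the expected maximum of Rayleigh noise
over the pixel count (`σ sqrt(2 ln n)`), since a plain 6 dB-over-median
rule admits a few percent of pure-noise pixels.

## Reconstruction

The source map at a hypothesised depth is recovered by a stationary Wiener
filter `P*/(|P|² + N·max|P|²)` applied to the demodulated image after
subtracting the boundary-driven term (zero for a phantom in ambient
equilibrium).  N is a dimensionless noise-to-signal level; the default is
estimated from the mean spectral power in the top decile of |k|, where the
strongly low-pass TPSF leaves essentially no signal.  A literal variant
with the measured spectrum inside the denominator exists behind a flag for
comparison studies; it is not a stationary filter and is not the default
because the standard form is the only dimensionally consistent reading.
The returned map is the magnitude of the complex estimate.  Regularisation
monotonically smooths noisy reconstructions; on a perfectly noiseless step
the first whisper of low-passing adds Gibbs ripple, so the
smoothness-vs-N property is only meaningful (and only asserted) for noisy
inputs.

Depth-from-phase minimises the summed squared wrapped-phase residual
between observed TPSF peak phases and the model curve over the deepest
layer (coarse scan of 60 points, then bounded refinement).  A single
frequency can alias through phase wrapping; two or more frequencies jointly
give a unique minimum.

## Phantom simulator

The generator reproduces the calibration phantom: a 14-mm polyester slab
(κ = 0.155 W/m/K, ρ = 1090 kg/m³, C = 1670 J/kg/K, D = 8.52·10⁻⁸ m²/s)
holding eleven 120 Ω resistors with 3 × 1.7 mm footprint — five at 3 mm
depth spaced 4.2 mm, three at 5 mm spaced 8.4 mm, three at 7 mm spaced
16.8 mm, rows separated by 21 mm transversely.  Resistor bodies lie along
the row; the 1.7 mm width faces the FWHM scan axis, which is what the
resolution metric subtracts.  A sine of amplitude A (default 7.2 V) across
R dissipates `A²/2R` as DC plus an equal AC amplitude at twice the
electrical frequency; 7.2 V across 120 Ω gives 0.432 W of heat in total.
The camera records 75 frames per electrical stimulation cycle (pixel pitch
0.4 mm, matching a 320-px camera at the study's working distance), 12
cycles by default, with additive white sensor noise of σ = 0.05 K per pixel
per frame — a representative uncooled-camera figure, configurable.  Top
convection defaults to 10 W/m²K (free air); the bottom is insulated.
Sources are planar sheets at the nominal depth by default; a volumetric
option spreads them over a 1 mm height for sensitivity studies (at 0.1 Hz
the axial decay length is ~0.5 mm, so this is a visible but
footprint-preserving perturbation).

Frames are synthesised directly in the quasi-steady regime
(`baseline + τ_DC + Re{τ_AC e^{jωt}}` plus noise), deterministic under a
fixed seed; a seed is mandatory whenever noise is on.  `transient_stack`
instead time-steps the finite-difference solver from a uniform start, for
exercising the truncation logic on non-sinusoidal early frames.

What the generator does *not* emulate: camera nonuniformity, emissivity and
radiometric calibration, resistor-to-resistor amplitude drift and booster
instability, petri-dish side walls, and perfused tissue.  Passing tests
therefore demonstrate correctness of the model, processing and inversion
chain under ideal sensing, not robustness to those instrument effects.

## Finite-difference validation solver

An explicit cell-centred scheme on a z-layered box: harmonic-mean face
conductivities at material interfaces, Robin faces entered through the
series resistance of the convective film and the half-cell of solid,
zero-gradient transverse truncation on a padded domain, time step at 90% of
the von Neumann bound.  It exists to validate the spectral solver at small
sizes (≤ 64³), not to be fast.  `steady_periodic` settles for six transient
time constants — the larger of the slab diffusion mode `(2z_N/π)²/D` and
the lumped convective constant `ρC z_N / h`, which dominates for weakly
convective slabs — then demodulates whole cycles per cell, checking
cycle-over-cycle drift (1%) unless the coherent component is buried under
the DC field (a pure-DC drive leaves only start-up residue in the signal
bin).  Comparisons against the spectral solver are made at the FD cell
centres (surface cell at hz/2), with the source sheet aligned to the centre
of the FD source cell; on a 32×32×24 grid at 0.005 Hz the two agree to
~0.5% RMS of peak and ~0.04 rad magnitude-weighted phase.

## Problem sizes

Default test and reproduction runs use grids of 48²–256² pixels, FD grids
up to 32×32×28, 20 randomized reconstruction scenes, and simulated
recordings of up to 24 cycles (≤ 1800 frames) — sizes chosen so the full
suite completes in well under a minute while every tolerance above is
exercised at its stated value.

## Known limitations

- Sources must live in the deepest layer (as in the study geometry);
  shallower-layer sources would need per-layer particular solutions.
- Reconstruction is per-hypothesised-depth; no joint 3-D inversion.
- The depth profile at very large |k|·z relies on cancellation between
  scaled coefficients and loses accuracy; surface quantities are immune
  (the scaling cancels exactly there).
- The five-source 3-mm row at 0.1 Hz produces along-row valleys at ~0.55 of
  peak in the noiseless model, so per-hotspot FWHM in merged rows is only
  measurable across the row; detection still separates the five peaks.
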