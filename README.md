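# thermolock

Lock-in thermography of buried heat sources: a layered-medium bio-heat
forward model, temporal demodulation of thermal camera recordings, and
Wiener deconvolution that together estimate the transverse distribution and
depth of heat sources several millimetres under an imaged surface.

The intended user images a surface with a thermal camera while the buried
sources (resistors in a calibration phantom, RF-excited nanoparticles in
tissue) are driven with a known low-frequency modulation, and wants the
source map at depth rather than the diffusion-blurred surface picture.

## Model

Neglecting perfusion and metabolic terms, the temperature rise per layer
obeys a diffusion equation.  With a time-harmonic drive
`q(r, t) = q_DC(r) + q_AC(r) cos(ω t)` and a transverse Fourier transform
`T(k_x, k_y, z)`, each layer reduces to the ODE

    d²T/dz² − μ² T = −Q(k, z)/κ,      μ = sqrt(k_x² + k_y² + j ω / D),

whose solutions `A e^{+μz} + B e^{−μz}` are chained across layer interfaces
by 2×2 transfer matrices (temperature and flux continuity) and closed by
convective (Robin) conditions at both faces.  The response to a source sheet
at depth `z_s` defines the thermal point-spread function `P(k_x, k_y)` — the
blur kernel between the buried source map and the complex surface image.
Demodulating the camera frames at the modulation frequency gives that
complex image; the source map is recovered with the stationary Wiener filter

    q̂ = F⁻¹[ P* F{τ − τ_BC} / (|P|² + N |P|²_max) ].

Because resistive heating goes as V², a sinusoidal drive at `f_elec` heats
at DC and at `2 f_elec` in equal parts — the demodulation frequency is the
doubled one.

Modules: `thermolock.model` (spectral solver and TPSF), `thermolock.lockin`
(demodulation, SNR, FWHM/resolution/visibility metrics),
`thermolock.reconstruct` (Wiener deconvolution, depth from phase),
`thermolock.phantom` (synthetic resistor-phantom recordings),
`thermolock.fd` (explicit finite-difference validation solver),
`thermolock.config` / `thermolock.cli` (YAML-configured workflow).

## Worked example

A single 120 Ω resistor 3 mm deep in a 14-mm polyester slab, driven by a
7.2 V sine at 0.05 Hz (0.432 W of heat, half of it in the 0.1 Hz AC term),
recorded for 12 modulation cycles with 0.05 K sensor noise, then
demodulated and deconvolved (`examples/phantom.yaml`):

```sh
thermolock pipeline --config examples/phantom.yaml --seed 1 --out-dir out/demo
```

```json
{
  "config_hash": "7789f994701c9baf",
  "f_demod_hz": 0.1,
  "mean_snr_db": 12.46497397598663,
  "transverse_resolution_mm": 1.2946389802398268,
  "n_hotspots": 1,
  "source_peak_w_m2": 46606.494957971336
}
```

Reading the numbers: the coherent 0.1 Hz component stands 12.5 dB over the
per-bin noise in the central region of interest; the demodulated hotspot is
1.29 mm wider (FWHM) than the 1.7 mm resistor width — the transverse thermal
resolution; and the Wiener-reconstructed source map peaks at 47 kW/m²,
close to the true areal density of the drive (0.216 W over 3 × 1.7 mm ≈
42 kW/m²).  The kernel itself is summarised by:

```sh
thermolock tpsf --config examples/phantom.yaml --out-dir out/demo \
    --depth-mm 3 --f-thermal-hz 0.1
```

```json
{"depth_mm": 3.0, "f_thermal_hz": 0.1, "fwhm_mm": 2.827136933080268,
 "peak_db": 0.4932410268997794, "peak_phase_rad": 0.5349217486961089}
```

Deeper sources and lower frequencies widen this kernel; the peak phase
varies with depth and is the handle `thermolock.reconstruct.depth_from_phase`
uses to estimate `z_s`, with a second frequency resolving phase-wrap
ambiguity.

Other subcommands: `simulate`, `demod`, `metrics`, `reconstruct`, and
`validate` (spectral solver against the finite-difference solver, with a
pass/fail RMS report).

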