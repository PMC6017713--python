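# Single shallow resistor of the polyester phantom, driven at 0.05 Hz
# electrical (0.1 Hz thermal), imaged noisily and reconstructed at 3 mm.
phantom:
  groups:
    - {depth_mm: 3.0, count: 1, spacing_mm: 4.2}
drive:
  amplitude_v: 7.2
  f_elec_hz: 0.05
  mask: [true]
camera:
  nx: 96
  ny: 72
  pixel_mm: 0.6
  cycles: 12
  noise_sigma_k: 0.05
processing:
  snr_roi: [30, 42, 42, 54]   # central patch around the hotspot
reconstruction:
  depth_mm: 3.0
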