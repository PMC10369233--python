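# Gaussian band model for synthetic C-H-region SRS reference spectra.
# Centers/widths in cm^-1 (width = Gaussian sigma), amplitudes in arbitrary
# SRS units before area normalization. Saturated fatty acids: every CH2 band
# amplitude is multiplied by (n - 2) for chain length n (internal methylene
# count grows with the chain, the terminal methyl does not). Widths emulate
# the ~25 cm^-1 effective spectral resolution of chirped femtosecond SRS.
axis:
  start: 2800.0
  stop: 3050.0
  n: 40
ch2_bands:            # methylene stretches, inside the 2832-2888 window
  - {center: 2850.0, width: 12.0, amplitude: 1.0}
  - {center: 2880.0, width: 9.0, amplitude: 0.45}
ch3_bands:            # terminal methyl stretches, inside the 2909-2967 window
  - {center: 2935.0, width: 14.0, amplitude: 6.0}
  - {center: 2960.0, width: 10.0, amplitude: 4.0}
# Acyl-chain packing subtly shifts and broadens the C-H bands with chain
# length (a few cm^-1 across C6-C20). Without these terms all saturated
# model spectra would be exact linear mixtures of two shapes and the
# per-species unmixing problem would be degenerate by construction.
saturated_center_shift_per_carbon:
  ch2: 0.8
  ch3: -0.5
saturated_width_slope_per_carbon: 0.02
unsaturated_bands:    # broad dominant band plus the =C-H marker near 3000
  - {center: 2900.0, width: 38.0, amplitude: 1.00}
  - {center: 2852.0, width: 13.0, amplitude: 0.30}
  - {center: 3002.0, width: 15.0, amplitude: 1.30}
protein_bands:        # broad CH3-dominated protein envelope (BSA-like)
  - {center: 2930.0, width: 40.0, amplitude: 1.00}
  - {center: 2875.0, width: 23.0, amplitude: 0.35}
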