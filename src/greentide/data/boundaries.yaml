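# Boundary conditions for the opportunistic-macroalgae bloom assessment sub-metrics.
# Each sub-metric maps six anchor values to the fixed EQR anchors
# 1.0, 0.8, 0.6, 0.4, 0.2, 0.0 (lower limit, High/Good, Good/Moderate,
# Moderate/Poor, Poor/Bad, upper limit).  Values between anchors are scored
# by linear interpolation; values above the upper limit clamp to EQR 0.
version: 1
eqr_anchors: [1.0, 0.8, 0.6, 0.4, 0.2, 0.0]
metrics:
  cover_pct_aih:        [0, 5, 15, 25, 75, 100]
  biomass_aih:          [0, 100, 500, 1000, 3000, 6000]
  biomass_aa:           [0, 100, 500, 1000, 3000, 6000]
  entrained_pct:        [0, 1, 5, 20, 50, 100]
  aa_ha:                [0, 10, 50, 100, 250, 6000]
  aa_over_aih_pct:      [0, 5, 15, 50, 75, 100]
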