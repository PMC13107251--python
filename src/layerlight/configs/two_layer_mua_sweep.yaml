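# Two-layer sweep: vary superficial absorption at each top-layer thickness.
model: two-layer
l1_grid: [8.0, 10.0, 12.0, 14.0, 16.0]
varied: mua1
# Grid brackets the nominal superficial absorption (0.017).  Below
# mua1 ~ 0.012 the phase-family depth-sensitivity hierarchy inverts in
# the three-layer (CSF) model (see docs/methods.md); extend at will.
values: [0.014, 0.017, 0.021, 0.025]
constants:
  mua2: 0.021
  musp1: 1.45
  musp2: 1.1
n_photons: 10000000
seed: 7
delta_deep: 0.001
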