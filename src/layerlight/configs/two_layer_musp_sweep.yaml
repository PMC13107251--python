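# Two-layer sweep: vary superficial reduced scattering (new MC per value).
model: two-layer
l1_grid: [8.0, 10.0, 12.0, 14.0, 16.0]
varied: musp1
values: [0.4, 1.8]
constants:
  mua1: 0.017
  mua2: 0.021
  musp2: 1.1
n_photons: 10000000
seed: 7
delta_deep: 0.001
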