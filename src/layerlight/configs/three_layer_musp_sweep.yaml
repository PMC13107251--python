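# Three-layer sweep (2 mm clear middle layer): vary superficial scattering.
model: three-layer
l1_grid: [8.0, 10.0, 12.0, 14.0, 16.0]
varied: musp1
values: [0.4, 1.8]
constants:
  mua1: 0.017
  mua3: 0.021
  musp3: 1.1
n_photons: 10000000
seed: 7
delta_deep: 0.001
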