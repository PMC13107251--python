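# Methods

This note records the physical models, numerical choices, and scope of the
synthetic-data generators in `layerlight`. Everything here describes the
package's own choices; tolerances quoted in the test suite were fixed before
the corresponding measurements were made.

## Geometry and measurement array

Media are stacks of horizontal slabs inside a wide bounding box (600 mm
lateral, 200 mm deep by default), each layer with absorption `mua`,
reduced scattering `musp` (isotropic scattering is simulated at `musp`
directly — equivalent to anisotropic scattering at `mus = musp/(1-g)` under
the similarity relation), and refractive index `n = 1.4` against air.

The default measurement array is a linear *dual-slope* (DS) set: two
sources and two detectors arranged so each source sees one detector at
`rho = 25 mm` and the other at `37 mm`, giving two mirrored source–detector
pairs per distance. Six data types are formed per wavelength:

| name | definition |
|---|---|
| `sdi25`, `sdi37` | single-distance `ln(rho^2 I)` at 25 / 37 mm (mirror pairs averaged) |
| `sdphi25`, `sdphi37` | single-distance phase (rad) |
| `dsi`, `dsphi` | dual slopes: mean of the two per-source two-point slopes vs `rho` |

The dual slopes are *self-calibrating*: a complex coupling factor attached
to any one source or detector cancels exactly (verified to 1e-13 in the
tests).

## White Monte Carlo with a per-layer path ledger

`run_white_mc` propagates photons with zero absorption and records, for
every detected photon, its path length in each layer (the *ledger*). The
frequency-domain reflectance at modulation `f = 140.625 MHz`
(`omega = 2 pi f`) for any absorption assignment `mua_j` is then

    R~ = (1 / (N A)) * sum_k exp(-sum_j mua_j l_jk) * exp(+i omega sum_j l_jk n_j / c)

so one simulation serves an entire absorption grid exactly, and derivatives
with respect to any layer's absorption are analytic:

    dR~/dmua_j = -(1 / (N A)) * sum_k l_jk exp(...) ,

exact to machine precision (locked at 1e-6 relative against central finite
differences in the acceptance tests).

Implementation choices:

- **RNG**: an inline xorshift64* generator inside the `numba`-compiled
  kernel; per-source streams seeded from `SeedSequence(seed)`, all seeds
  kept below 2^31. Runs are bit-identical under a fixed seed.
- **Tally**: annular rings of 2 mm width at the nominal distances
  (default), exploiting the lateral symmetry of the slab geometry for a
  much larger effective detector than a physical disc; a `disc` mode is
  available for comparison.
- **Path cutoff** (`max_path`): photons are abandoned once their total path
  exceeds the cutoff. For production runs at 1e7 photons the test suite
  uses 700 mm: at the smallest fitted absorption encountered
  (0.0139 mm^-1) such a path carries relative weight `exp(-9.7)`, so the
  truncation bias is far below the Monte Carlo noise. The library default
  is a conservative 2000 mm.
- **Boundary**: Fresnel reflection/refraction at the top surface
  (`n = 1.4` to air), matching the closed-form normal-incidence coefficient
  0.0278 in the tests.

## Diffusion model, absolute fit, and retrieval

The homogeneous reference model is the semi-infinite extrapolated-boundary
diffusion solution with `D = 1/(3 musp)`, source depth `z0 = 1/musp`,
extrapolation distance `zb = 2 D (1+Reff)/(1-Reff)` with `Reff(1.4) = 0.493`,
and complex attenuation `k = sqrt((mua - i omega n/c)/D)` chosen with
`Re k > 0`, `Im k < 0` so phase grows with distance.

`fit_absolute_properties` inverts the two measured dual slopes for the
effective homogeneous `(mua, musp)`: an infinite-medium closed-form initial
guess followed by a damped Newton iteration on the semi-infinite model
(forward-difference 2x2 Jacobians, residual tolerance 1e-9 mm^-1).
Round-trip accuracy on model-generated slopes is locked at 0.1% over
`mua in [0.005, 0.025]`, `musp in [0.4, 1.8] mm^-1`.

Small data-type changes are converted to *effective absorption changes*
`Delta mua_M = Delta M / J_M` through homogeneous Jacobians computed by
central differences with step 1e-5 mm^-1 (step-halving stable to 1e-4).
This retrieval is a linearization: its error grows roughly linearly with
amplitude (about 1% at `Delta mua = 1e-4`, a few percent at 1e-3).

## Layer sensitivity and two-layer separation

For a layered ledger, per-layer data-type derivatives are assembled exactly
from the path ledger. The sensitivity of data type `M` to layer `i` is the
derivative normalised by the sum over *all* layers (the CSF layer
participates in the normalisation but is not solved for), giving a 6x2
matrix over the superficial and cerebral layers. A measurement vector of
six effective absorption changes is separated with the Moore–Penrose
pseudoinverse; SEMs propagate as
`var(layer) = sum_M (S+)^2 sem_M^2` under uncorrelated noise.

## Reference head models

The campaign and test geometries use a superficial layer with
`mua1 = 0.017 mm^-1` and varying `musp1` and thickness `L1`, over a deep
layer with `mua = 0.021`, `musp = 1.1 mm^-1`; the three-layer variant
inserts a 2 mm CSF layer (`mua = 0.0027`, `musp = 0.01 mm^-1`). Locked
reference values for the fitted effective properties at 1e7 photons
(tolerance 5%):

| geometry | fitted value |
|---|---|
| three-layer, `L1 = 10`, `musp1 = 0.75` | `mua = 0.0144`, `musp = 0.45` |
| three-layer, `L1 = 14`, `musp1 = 0.75` | `musp = 0.70` |
| two-layer, `L1 = 10`, `musp1 = 0.40` | `mua = 0.0214` |
| two-layer, `L1 = 10`, `musp1 = 1.80` | `mua = 0.0173`, `musp = 1.64` |

`scripts/acceptance.py` recomputes these six values from scratch.

For a deep absorption step the retrieved effective changes are ordered
`sdi25 < sdi37 < dsi` and `sdphi25 < sdphi37 < dsphi` (longer distances and
slopes weigh the deep layer more). The tests verify this over both models
and `L1 in {10, 12, 14} mm`, varying one superficial parameter at a time:
`mua1 in {0.014, 0.017, 0.021, 0.025}` at `musp1 = 1.45`, and
`musp1 in {0.4, 1.8}` at `mua1 = 0.017` — the default sweep grids shipped
in `configs/`.

**A finding of this implementation**: the phase-family ordering is *not*
universal. In the three-layer (CSF) model at `musp1 = 1.45` the phase
hierarchy inverts (`sdphi25 > sdphi37 > dsphi`) once the superficial
absorption drops below roughly `0.012 mm^-1` (at `L1 = 10–12 mm`); the
crossover is robust to the Monte Carlo path cutoff (verified at 700 and
2000 mm) and appears at joint low superficial absorption and scattering in
the two-layer model as well. The default absorption grids therefore start
at 0.014; users extending them below the crossover will see the inversion.

A second branch of the same crossover surface passes through the
three-layer point `musp1 = 0.4`, `L1 = 10 mm` at the nominal
`mua1 = 0.017`: eight independent 4e6-photon replicates put the phase
margins at `sdphi37/sdphi25 - 1 = -0.60% ± 0.24%` and
`dsphi/sdphi37 - 1 = -0.97% ± 0.39%` at the production path cutoff
(`-0.34% ± 0.23%` and `-0.55% ± 0.37%` at 2000 mm) — slightly *inverted*,
with single 1e7-photon runs straddling zero. The intensity family remains
strongly ordered there (+25% and +38% margins). Because this point's
coordinates are part of the reference head models, the ordering test in
the acceptance suite keeps its strict assertion and *fails by design* at
exactly this configuration; the failure message lists the violating
point. The CSF layer is the driver: the two-layer model at the same
superficial scattering orders correctly.

## Functional generator and analysis chain

The block protocol is 60 s baseline + 7 x (15 s stimulus + 30 s rest) +
60 s baseline at 10 Hz. The planted response is a difference-of-gammas
kernel (shape 4, 2 s onset delay, 6 s rise time) scaled to a chosen peak
`Delta mua`. The default time constants make the peak broad enough
(SD ~4 s) that the analysis chain's smoothing flattens it by under ~5%; a
much narrower response would be clipped by the smoothing regardless of
signal-to-noise.

Instrument noise is drawn per physical channel (four ln-intensity, four
phase) and combined into the six data types, preserving their correlation
structure; defaults are 0.002 (ln-intensity) and 0.003 rad per sample.

The analysis chain folds the traces over the seven cycles, smooths with a
3 s centred moving average, estimates noise `sigma` as the sample SD of the
*pre-smoothing* folded trace over the 20–22 s rest segment, detects a peak
when the smoothed maximum exceeds `3 sigma`, and reports the mean over a
±1 s window around the peak. The pre-smoothing sigma is deliberate: the
moving average correlates neighbouring samples so strongly that a sigma
estimated on the smoothed trace would make the threshold fire on pure
noise. Locked performance: a planted 1e-3 mm^-1 peak recovered within 10%
under default noise, and at most 5% false detections over 100 noise-only
seeds.

When a generated series carries forward-model Jacobians, the pipeline folds
the retrieved `Delta mua(t) = Delta M(t)/J_M` traces so an absorption
increase peaks positively in every data type; on raw `Delta M` tables the
intensity types respond negatively and a `polarity` option selects the
expected sign.

## Limitations

- The Monte Carlo is layered-slab only: no lateral structure, no curvature,
  and a single refractive index (1.4) for all tissue layers.
- The two-layer separation assumes the sensitivity matrix of the *assumed*
  geometry; errors in layer thickness map into attribution errors that the
  package does not model.
- The diffusion model used by the fit is homogeneous and semi-infinite;
  the fitted `(mua, musp)` on layered media are *effective* values by
  construction, not properties of any single layer.
- Beer's law uses a two-wavelength, two-chromophore inversion with shipped
  extinction values at 660/690/750/830 nm only.
- The functional generator plants a single deterministic kernel per layer;
  it validates the analysis chain, it does not emulate physiology
  (optional sinusoidal "physiological" oscillations are available but
  rudimentary).
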