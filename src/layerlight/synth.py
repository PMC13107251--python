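"""Synthetic functional dual-slope FD-NIRS time series.

Emulates the block-design visual-stimulation experiment: an initial 60 s
rest baseline, seven cycles of 15 s stimulus + 30 s rest, and a final 60 s
baseline.  A planted hemodynamic response kernel drives an absorption change
in the deepest (cerebral) layer — optionally also the superficial layer —
which is pushed through the layered forward model to produce data-type
changes Delta M(t), plus additive instrument noise and optional
physiological oscillations.

The response kernel is deliberately synthetic: the block protocol fixes the
timing, but no particular response shape is assumed by the analysis chain,
so the generator's role is to provide a *known* planted truth for pipeline
validation, not physiological fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .engine import DATA_TYPES, DataTypeVector, compute_datatypes, delta_datatypes
from .forward import OMEGA_DEFAULT, homogeneous_jacobian, layer_derivatives
from .inversion import datatype_layer_derivatives

__all__ = [
    "ProtocolDefinition",
    "FunctionalTimeSeries",
    "hemodynamic_kernel",
    "generate_functional_run",
]

#: Default per-sample instrument noise (10 Hz): ln-intensity channels are
#: dimensionless, phase channels in rad.
DEFAULT_NOISE_SD = {"lnI": 0.002, "phase": 0.003}


@dataclass(frozen=True)
class ProtocolDefinition:
    """Block-design stimulation protocol timing."""

    baseline_pre: float = 60.0
    n_cycles: int = 7
    stim_s: float = 15.0
    rest_s: float = 30.0
    baseline_post: float = 60.0
    sample_rate: float = 10.0

    @property
    def cycle_s(self) -> float:
        return self.stim_s + self.rest_s

    @property
    def duration(self) -> float:
        return self.baseline_pre + self.n_cycles * self.cycle_s + self.baseline_post

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def annotations(self) -> list[tuple[float, float, str]]:
        """(start, end, label) blocks tiling the protocol."""
        blocks = [(0.0, self.baseline_pre, "baseline")]
        t = self.baseline_pre
        for _ in range(self.n_cycles):
            blocks.append((t, t + self.stim_s, "stimulus"))
            blocks.append((t + self.stim_s, t + self.cycle_s, "rest"))
            t += self.cycle_s
        blocks.append((t, t + self.baseline_post, "baseline"))
        return blocks

    def cycle_starts(self) -> np.ndarray:
        return self.baseline_pre + self.cycle_s * np.arange(self.n_cycles)


def hemodynamic_kernel(
    t,
    peak_dmua: float,
    onset_delay: float = 2.0,
    rise_tau: float = 6.0,
    fall_tau: float = 6.0,
    undershoot: float = 0.1,
) -> np.ndarray:
    """Difference-of-gammas response over one stimulus-rest cycle.

    Zero before ``onset_delay``, peaks ``rise_tau`` seconds later (during
    the 15 s stimulus for the defaults), and relaxes toward zero on the
    ``fall_tau`` timescale with a small undershoot.  The curve is scaled so
    its maximum equals ``peak_dmua`` (mm^-1).

    The default time constants give a peak broad enough (SD ~4 s) that the
    analysis chain's 3 s moving average plus ±1 s window averaging flattens
    the maximum by under ~5%; a much narrower planted response would be
    clipped by the smoothing regardless of signal-to-noise ratio.
    """
    if rise_tau <= 0 or fall_tau <= 0:
        raise ValueError("time constants must be positive")
    t = np.asarray(t, float)
    if peak_dmua == 0.0:
        return np.zeros_like(t)
    tp = t - onset_delay
    shape = 4.0
    main = gamma_dist.pdf(tp, shape, scale=rise_tau / (shape - 1.0))
    late = gamma_dist.pdf(tp, shape, scale=(rise_tau + fall_tau) / (shape - 1.0))
    h = main / main.max() - undershoot * late / late.max()
    return peak_dmua * h / h.max()


@dataclass
class FunctionalTimeSeries:
    """Sampled data-type traces with protocol annotations and planted truth.

    ``data`` columns are the six data types (Delta M relative to the initial
    baseline); ``truth`` holds the planted per-layer Delta mua(t) traces and
    generator parameters.
    """

    time: np.ndarray
    data: pd.DataFrame
    protocol: ProtocolDefinition
    wavelength: float = 830.0
    ds_set_id: int = 0
    truth: dict = field(default_factory=dict)
    noise_meta: dict = field(default_factory=dict)
    seed: int | None = None
    jacobians: dict | None = None

    def retrieve_dmua(self, jacobians: dict | None = None) -> pd.DataFrame:
        """Per-type effective Delta mua(t) = Delta M(t) / J_M."""
        jac = jacobians or self.jacobians
        if jac is None:
            raise ValueError("no Jacobians available; pass them explicitly")
        out = {m: self.data[m] / jac[m] for m in DATA_TYPES}
        return pd.DataFrame(out, index=self.data.index)

    def to_csv(self, path, sidecar_path=None) -> None:
        df = self.data.copy()
        df.insert(0, "ds_set_id", self.ds_set_id)
        df.insert(0, "wavelength_nm", self.wavelength)
        df.insert(0, "time_s", self.time)
        df.to_csv(path, index=False)
        if sidecar_path is not None:
            import json

            meta = {
                "protocol": self.protocol.__dict__,
                "wavelength_nm": self.wavelength,
                "seed": self.seed,
                "noise": self.noise_meta,
                "truth_params": {
                    k: v for k, v in self.truth.items() if np.isscalar(v)
                },
            }
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=1)


def _block_response(protocol: ProtocolDefinition, peak: float, kernel_kw: dict) -> np.ndarray:
    """Kernel tiled over the stimulus cycles; zero in the two baselines."""
    t = protocol.times()
    out = np.zeros_like(t)
    if peak == 0.0:
        return out
    for start in protocol.cycle_starts():
        in_cycle = (t >= start) & (t < start + protocol.cycle_s)
        out[in_cycle] += hemodynamic_kernel(t[in_cycle] - start, peak, **kernel_kw)
    return out


def generate_functional_run(
    medium=None,
    ledger=None,
    protocol: ProtocolDefinition | None = None,
    deep_peak_dmua: float = 0.001,
    superficial_peak_dmua: float = 0.0,
    noise_sd: dict | None = None,
    physio_oscillations: dict | None = None,
    seed: int = 0,
    omega: float = OMEGA_DEFAULT,
    wavelength: float = 830.0,
    baseline_props: tuple[float, float] | None = None,
    path: str = "linear",
    kernel_kw: dict | None = None,
    ds_set_id: int = 0,
) -> FunctionalTimeSeries:
    """Generate one functional run of Delta M(t) for a DS set.

    Forward model routes:

    * analytic (``medium`` homogeneous or ``baseline_props`` given, no
      ledger): Delta M(t) = J_M * Delta mua_deep(t) with homogeneous
      Jacobians — the deep layer is the whole medium;
    * ledger (``ledger`` from a layered white MC): per-layer data-type
      derivatives map the planted superficial and deep Delta mua(t) into
      Delta M(t) to first order (``path="linear"``), or Delta M(t) is
      re-assembled exactly from the ledger at every distinct amplitude
      (``path="exact"``).

    Additive Gaussian instrument noise is drawn per SD channel (four
    ln-intensity and four phase channels) and combined into the six data
    types, preserving their correlation structure; optional physiological
    sinusoids (cardiac ~1 Hz, vasomotion ~0.1 Hz) ride on the superficial
    layer.  Bit-identical reproducibility under a fixed seed.
    """
    protocol = protocol or ProtocolDefinition()
    kernel_kw = kernel_kw or {}
    noise = DEFAULT_NOISE_SD if noise_sd is None else dict(noise_sd)
    if any(v < 0 for v in noise.values()):
        raise ValueError("noise standard deviations must be nonnegative")
    t = protocol.times()
    rng = np.random.default_rng(seed)

    d_deep = _block_response(protocol, deep_peak_dmua, kernel_kw)
    d_sup = _block_response(protocol, superficial_peak_dmua, kernel_kw)
    if physio_oscillations:
        cardiac = physio_oscillations.get("cardiac_amp", 0.0)
        vaso = physio_oscillations.get("vaso_amp", 0.0)
        f_card = physio_oscillations.get("cardiac_hz", 1.0)
        f_vaso = physio_oscillations.get("vaso_hz", 0.1)
        ph = rng.uniform(0, 2 * np.pi, size=2)
        d_sup = d_sup + cardiac * np.sin(2 * np.pi * f_card * t + ph[0]) \
            + vaso * np.sin(2 * np.pi * f_vaso * t + ph[1])

    jac = None
    if ledger is not None:
        mua = ledger.medium.mua if ledger.medium is not None else None
        if mua is None:
            raise ValueError("ledger lacks its medium; cannot set baseline absorption")
        derivs = layer_derivatives(ledger, mua, omega)
        rows = datatype_layer_derivatives(derivs)  # (6, Nl)
        if path == "linear":
            dM = rows[:, -1][:, None] * d_deep[None, :] + rows[:, 0][:, None] * d_sup[None, :]
        elif path == "exact":
            dM = _exact_dM(ledger, mua, omega, d_sup, d_deep)
        else:
            raise ValueError(f"unknown path {path!r}")
        jac = dict(zip(DATA_TYPES, rows.sum(axis=1)))
    else:
        if baseline_props is not None:
            mua0, musp0 = baseline_props
        elif medium is not None and len({(l.mua, l.musp) for l in medium.layers}) == 1:
            mua0, musp0 = medium.layers[0].mua, medium.layers[0].musp
        else:
            raise ValueError(
                "analytic route needs a homogeneous medium or explicit "
                "baseline_props; pass a ledger for layered media"
            )
        jac = homogeneous_jacobian(mua0, musp0, omega)
        jrow = np.array([jac[m] for m in DATA_TYPES])
        dM = jrow[:, None] * (d_deep + d_sup)[None, :]

    # per-channel noise: four lnI + four phase channels of the DS set
    s_ln = noise.get("lnI", 0.0)
    s_ph = noise.get("phase", 0.0)
    eps_ln = rng.normal(0.0, s_ln, size=(2, 2, t.size)) if s_ln > 0 else np.zeros((2, 2, t.size))
    eps_ph = rng.normal(0.0, s_ph, size=(2, 2, t.size)) if s_ph > 0 else np.zeros((2, 2, t.size))
    drho = 12.0
    noise_rows = np.vstack(
        [
            eps_ln[:, 0].mean(axis=0),                      # sdi25: mean over mirror pair
            eps_ln[:, 1].mean(axis=0),                      # sdi37
            eps_ph[:, 0].mean(axis=0),                      # sdphi25
            eps_ph[:, 1].mean(axis=0),                      # sdphi37
            (eps_ln[:, 1] - eps_ln[:, 0]).mean(axis=0) / drho,  # dsi
            (eps_ph[:, 1] - eps_ph[:, 0]).mean(axis=0) / drho,  # dsphi
        ]
    )
    dM = dM + noise_rows

    data = pd.DataFrame(dM.T, columns=list(DATA_TYPES))
    return FunctionalTimeSeries(
        time=t,
        data=data,
        protocol=protocol,
        wavelength=wavelength,
        ds_set_id=ds_set_id,
        truth={
            "deep_peak_dmua": deep_peak_dmua,
            "superficial_peak_dmua": superficial_peak_dmua,
            "dmua_deep_t": d_deep,
            "dmua_superficial_t": d_sup,
        },
        noise_meta={"lnI_sd": s_ln, "phase_sd": s_ph},
        seed=seed,
        jacobians=jac,
    )


def _exact_dM(ledger, mua, omega, d_sup, d_deep) -> np.ndarray:
    """Re-assemble Delta M(t) from the ledger at each distinct amplitude pair.

    The block design repeats identical cycles, so the number of distinct
    (superficial, deep) amplitude pairs is one cycle's worth of samples.
    """
    from .forward import assemble_reflectance

    nl = ledger.n_layers
    base = compute_datatypes(assemble_reflectance(ledger, mua, omega))
    pairs = np.unique(np.column_stack([d_sup, d_deep]), axis=0)
    lut = {}
    for s_amp, d_amp in pairs:
        m = np.asarray(mua, float).copy()
        m[0] += s_amp
        m[-1] += d_amp
        if nl == 1:
            m[0] = mua[0] + s_amp + d_amp
        dtv = compute_datatypes(assemble_reflectance(ledger, m, omega))
        lut[(s_amp, d_amp)] = delta_datatypes(base, dtv).as_array()
    return np.column_stack([lut[(s, d)] for s, d in zip(d_sup, d_deep)])
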