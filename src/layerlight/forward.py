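"""Frequency-domain forward models.

Two routes to the complex reflectance R~ of an intensity-modulated source:

* ``assemble_reflectance`` re-weights a zero-absorption ("white") Monte Carlo
  path ledger: each detected photon contributes
  ``exp(-sum_j mua_j * l_jk) * exp(+i * omega * sum_j l_jk * n_j / c)``,
  normalised by launched photons and detector area.  Because absorption
  enters only through this exponential factor, a single ledger serves every
  absorption assignment exactly, and per-layer absorption derivatives are
  available in closed form.

* ``diffusion_reflectance`` is the analytic photon-density-wave solution for
  a homogeneous semi-infinite medium with extrapolated-boundary conditions
  (image-source construction), used by the self-calibrating dual-slope fit
  and for homogeneous Jacobians.

Sign convention: phase grows with distance (a lag), i.e. the complex wave
goes as exp(+i*k_i*r) with k_i > 0; the Monte Carlo phase factor above uses
the matching +i sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.integrate import quad

__all__ = [
    "C_MM_S",
    "OMEGA_DEFAULT",
    "ComplexReflectance",
    "LayerDerivatives",
    "assemble_reflectance",
    "perturbed_reflectance",
    "layer_derivatives",
    "diffusion_reflectance",
    "diffusion_datatypes",
    "homogeneous_jacobian",
    "effective_reflectance",
    "reflectance_to_frame",
]

#: Speed of light in vacuum, mm/s.
C_MM_S = 2.99792458e11

#: Default angular modulation frequency: 140.625 MHz.
OMEGA_DEFAULT = 2.0 * np.pi * 140.625e6


# ---------------------------------------------------------------------------
# Analytic homogeneous semi-infinite diffusion model
# ---------------------------------------------------------------------------

def _fresnel_unpolarized(cos_i: float, n_rel: float) -> float:
    """Unpolarized Fresnel reflectance for internal incidence, n_rel = n_in/n_out."""
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = n_rel * n_rel * sin_i2
    if sin_t2 >= 1.0:
        return 1.0
    cos_t = np.sqrt(1.0 - sin_t2)
    rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
    rp = (n_rel * cos_t - cos_i) / (n_rel * cos_t + cos_i)
    return 0.5 * (rs * rs + rp * rp)


@lru_cache(maxsize=32)
def reff_fresnel(n_rel: float) -> float:
    """Effective boundary reflectance R_eff for a relative index n_in/n_out.

    Computed from the Fresnel angular integrals
    R_phi = int 2 sin(t) cos(t) R_F(t) dt and
    R_j   = int 3 sin(t) cos^2(t) R_F(t) dt over [0, pi/2], with
    R_eff = (R_phi + R_j) / (2 - R_phi + R_j).  For n_rel = 1.4 this gives
    approximately 0.493.
    """
    if np.isclose(n_rel, 1.0):
        return 0.0
    r_phi = quad(lambda t: 2.0 * np.sin(t) * np.cos(t)
                 * _fresnel_unpolarized(np.cos(t), n_rel), 0.0, np.pi / 2)[0]
    r_j = quad(lambda t: 3.0 * np.sin(t) * np.cos(t) ** 2
               * _fresnel_unpolarized(np.cos(t), n_rel), 0.0, np.pi / 2)[0]
    return (r_phi + r_j) / (2.0 - r_phi + r_j)


def diffusion_reflectance(
    rho,
    mua: float,
    musp: float,
    omega: float = OMEGA_DEFAULT,
    n_in: float = 1.4,
    n_out: float = 1.0,
    *,
    reff: float | None = None,
    d_mode: str = "musp",
):
    """Complex reflectance of a homogeneous semi-infinite medium.

    Fluence rate at the physical boundary from the extrapolated-boundary
    image-source pair: a real isotropic source at depth z0 = 1/mus' and a
    negative image at -(z0 + 2*zb), zb = 2*D*(1+Reff)/(1-Reff).  The complex
    wavenumber satisfies k^2 = (mua - i*omega*n_in/c) / D; the root with
    positive real part is taken, giving a phase that increases with rho.

    Parameters
    ----------
    rho : float or array
        Source-detector distance(s), mm (> 0).
    d_mode : {"musp", "mua+musp"}
        Diffusion coefficient D = 1/(3*mus') (default, absorption-free) or
        D = 1/(3*(mua+mus')).
    """
    rho = np.asarray(rho, float)
    if np.any(rho <= 0):
        raise ValueError("rho must be positive")
    if mua < 0 or musp <= 0:
        raise ValueError("need mua >= 0 and musp > 0")
    if d_mode == "musp":
        D = 1.0 / (3.0 * musp)
    elif d_mode == "mua+musp":
        D = 1.0 / (3.0 * (mua + musp))
    else:
        raise ValueError(f"unknown d_mode {d_mode!r}")
    if reff is None:
        reff = reff_fresnel(round(n_in / n_out, 6))
    z0 = 1.0 / musp
    zb = 2.0 * D * (1.0 + reff) / (1.0 - reff)
    k = np.sqrt((mua - 1j * omega * n_in / C_MM_S) / D)  # Re > 0, Im < 0
    r1 = np.sqrt(rho * rho + z0 * z0)
    zi = z0 + 2.0 * zb
    r2 = np.sqrt(rho * rho + zi * zi)
    phi = (np.exp(-k * r1) / r1 - np.exp(-k * r2) / r2) / (4.0 * np.pi * D)
    return phi


_DATA_TYPES = ("sdi25", "sdi37", "sdphi25", "sdphi37", "dsi", "dsphi")


def diffusion_datatypes(
    mua: float,
    musp: float,
    omega: float = OMEGA_DEFAULT,
    rhos: tuple[float, float] = (25.0, 37.0),
    n_in: float = 1.4,
    **kw,
) -> dict:
    """The six data types predicted by the homogeneous diffusion model.

    Returns a dict with keys sdi25, sdi37 (ln(rho^2 I)), sdphi25, sdphi37
    (rad), dsi and dsphi (two-point slopes over ``rhos``, mm^-1 units).  The
    keys keep the 25/37 naming for any actual pair of distances.
    """
    r = np.asarray(rhos, float)
    R = diffusion_reflectance(r, mua, musp, omega, n_in=n_in, **kw)
    lnr2i = np.log(r * r * np.abs(R))
    phase = np.angle(R)
    # nearest-branch continuity within the pair
    phase[1] += 2.0 * np.pi * np.round((phase[0] - phase[1]) / (2.0 * np.pi))
    drho = r[1] - r[0]
    return {
        "sdi25": lnr2i[0],
        "sdi37": lnr2i[1],
        "sdphi25": phase[0],
        "sdphi37": phase[1],
        "dsi": (lnr2i[1] - lnr2i[0]) / drho,
        "dsphi": (phase[1] - phase[0]) / drho,
    }


def homogeneous_jacobian(
    mua: float,
    musp: float,
    omega: float = OMEGA_DEFAULT,
    rhos: tuple[float, float] = (25.0, 37.0),
    n_in: float = 1.4,
    *,
    data_type: str | None = None,
    step: float = 1e-5,
    **kw,
):
    """d(M)/d(mua) for the homogeneous medium, per data type.

    Central finite difference on :func:`diffusion_datatypes` with step
    ``step`` (mm^-1).  Returns a dict over the six data types, or a scalar if
    ``data_type`` is given.  Intensity-type Jacobians are negative; at these
    distances and modulation frequency the phase-type ones are negative too.
    """
    if len(set(np.round(rhos, 9))) < 2:
        raise ValueError("rhos must contain two distinct distances")
    up = diffusion_datatypes(mua + step, musp, omega, rhos, n_in, **kw)
    lo = diffusion_datatypes(mua - step, musp, omega, rhos, n_in, **kw)
    jac = {m: (up[m] - lo[m]) / (2.0 * step) for m in _DATA_TYPES}
    if data_type is not None:
        return jac[data_type]
    return jac


# ---------------------------------------------------------------------------
# Monte Carlo ledger re-weighting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComplexReflectance:
    """R~ for one source-detector (or source-ring) channel.

    ``value`` is in mm^-2 (per launched photon per detector area).  Standard
    errors of the real and imaginary parts are from the sample variance of
    the per-photon complex summands (treating non-detected photons as zero
    contributions); ``se_lnamp``/``se_phase`` project them along/across the
    phasor direction.
    """

    source: int
    detector: int
    rho: float
    omega: float
    value: complex
    se_re: float = 0.0
    se_im: float = 0.0
    n_detected: int = 0

    @property
    def amplitude(self) -> float:
        return abs(self.value)

    @property
    def phase(self) -> float:
        return float(np.angle(self.value))

    @property
    def se_lnamp(self) -> float:
        """SE of ln|R~| (component of the complex SE along the phasor)."""
        if self.amplitude == 0:
            return np.inf
        u = self.value / self.amplitude
        return float(np.hypot(self.se_re * u.real, self.se_im * u.imag) / self.amplitude)

    @property
    def se_phase(self) -> float:
        if self.amplitude == 0:
            return np.inf
        u = self.value / self.amplitude
        return float(np.hypot(self.se_re * u.imag, self.se_im * u.real) / self.amplitude)


@dataclass(frozen=True)
class LayerDerivatives:
    """Per-layer absorption derivatives of R~ for one channel (exact)."""

    source: int
    detector: int
    rho: float
    base: complex
    dR_dmua: np.ndarray  # (n_layers,) complex

    @property
    def dlnI_dmua(self) -> np.ndarray:
        """d ln(rho^2 I)/d mua_j  =  Re(dR_j / R)."""
        return (self.dR_dmua / self.base).real

    @property
    def dphase_dmua(self) -> np.ndarray:
        """d phase/d mua_j  =  Im(dR_j / R)."""
        return (self.dR_dmua / self.base).imag


def _channel_weights(ledger, mua_per_layer, omega):
    mua = np.asarray(mua_per_layer, float)
    if mua.shape != (ledger.n_layers,):
        raise ValueError(
            f"mua_per_layer must have length {ledger.n_layers}, got {mua.shape}"
        )
    if np.any(mua < 0):
        raise ValueError("negative absorption coefficient")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    w = np.exp(-(ledger.paths @ mua))
    if omega == 0.0:
        return w.astype(complex)
    phase = (omega / C_MM_S) * (ledger.paths @ ledger.layer_n)
    return w * np.exp(1j * phase)


def assemble_reflectance(ledger, mua_per_layer, omega: float = OMEGA_DEFAULT) -> dict:
    """Apply absorption and modulation to a white-MC ledger.

    Returns ``{(source, detector): ComplexReflectance}`` for every tallied
    channel.  Empty channels are rejected: downstream slope fitting on a
    channel with zero detected photons is meaningless.
    """
    if len(ledger) == 0:
        raise ValueError("empty ledger: no detected photons")
    summand = _channel_weights(ledger, mua_per_layer, omega)
    out = {}
    for (src, det), idx in ledger.channel_index.items():
        if idx.size == 0:
            raise ValueError(f"no detected photons on channel (source {src}, det {det})")
        n_launch = ledger.n_launched[src]
        norm = n_launch * ledger.detector_area[det]
        s = summand[idx]
        total = s.sum()
        value = total / norm
        # population variance over all launched photons, zeros included
        var_re = (np.sum(s.real**2) - total.real**2 / n_launch) / n_launch
        var_im = (np.sum(s.imag**2) - total.imag**2 / n_launch) / n_launch
        se_re = np.sqrt(max(var_re, 0.0) / n_launch) / ledger.detector_area[det]
        se_im = np.sqrt(max(var_im, 0.0) / n_launch) / ledger.detector_area[det]
        out[(src, det)] = ComplexReflectance(
            source=src,
            detector=det,
            rho=ledger.rho[(src, det)],
            omega=omega,
            value=complex(value),
            se_re=float(se_re),
            se_im=float(se_im),
            n_detected=int(idx.size),
        )
    return out


def perturbed_reflectance(
    ledger,
    mua_per_layer,
    delta_mua_per_layer,
    omega: float = OMEGA_DEFAULT,
) -> tuple[dict, dict]:
    """Baseline and perturbed reflectance from the *same* ledger.

    Sharing the photon set makes the two reflectances exactly correlated, so
    the difference Delta R~ carries far less Monte Carlo noise than two
    independent simulations would.
    """
    base = assemble_reflectance(ledger, mua_per_layer, omega)
    mua = np.asarray(mua_per_layer, float) + np.asarray(delta_mua_per_layer, float)
    pert = assemble_reflectance(ledger, mua, omega)
    return base, pert


def layer_derivatives(ledger, mua_per_layer, omega: float = OMEGA_DEFAULT) -> dict:
    """Exact dR~/dmua_j per channel: -<l_jk>-weighted ledger sum."""
    if len(ledger) == 0:
        raise ValueError("empty ledger: no detected photons")
    summand = _channel_weights(ledger, mua_per_layer, omega)
    out = {}
    for (src, det), idx in ledger.channel_index.items():
        norm = ledger.n_launched[src] * ledger.detector_area[det]
        s = summand[idx]
        base = s.sum() / norm
        deriv = -(ledger.paths[idx] * s[:, None]).sum(axis=0) / norm
        out[(src, det)] = LayerDerivatives(
            source=src,
            detector=det,
            rho=ledger.rho[(src, det)],
            base=complex(base),
            dR_dmua=deriv,
        )
    return out


def effective_reflectance(reflectances: dict) -> dict:
    """Convenience: map channel keys to complex values only."""
    return {k: r.value for k, r in reflectances.items()}


def reflectance_to_frame(reflectances: dict, wavelength_nm: float = 830.0):
    """Tabulate a reflectance set as a pandas DataFrame (CSV-ready)."""
    import pandas as pd

    rows = []
    for (src, det), r in sorted(reflectances.items()):
        rows.append(
            {
                "source": src,
                "detector": det,
                "rho_mm": r.rho,
                "amplitude": r.amplitude,
                "phase_rad": r.phase,
                "se_amp": r.se_lnamp * r.amplitude,
                "se_phase": r.se_phase,
                "omega_rad_s": r.omega,
                "wavelength_nm": wavelength_nm,
            }
        )
    return pd.DataFrame(rows)
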