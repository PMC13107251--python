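"""Dual-slope FD-NIRS data types, absolute-property fitting, and retrieval.

The six data types of a dual-slope set are single-distance ln(rho^2 I) and
phase at the short and long distances (mirror pairs at equal rho averaged),
and the dual slopes: the mean of the two single-source slopes of ln(rho^2 I)
and of phase versus rho.  The dual slopes are self-calibrating — any complex
coupling factor attached to one source or one detector cancels exactly.

``fit_absolute_properties`` inverts the two dual slopes for the effective
homogeneous (mua, mus') using the semi-infinite extrapolated-boundary
diffusion model: an infinite-medium closed-form initial guess followed by a
damped Newton refinement.  ``retrieve_dmua`` then converts measured data-type
changes into effective absorption changes through the homogeneous Jacobians,
and ``beer_lambert`` maps absorption changes at two wavelengths to oxy- and
deoxy-hemoglobin concentration changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .forward import (
    OMEGA_DEFAULT,
    ComplexReflectance,
    diffusion_datatypes,
    homogeneous_jacobian,
)

__all__ = [
    "DATA_TYPES",
    "DataTypeVector",
    "AbsoluteProperties",
    "EffectiveAbsorptionChange",
    "compute_datatypes",
    "delta_datatypes",
    "fit_absolute_properties",
    "retrieve_dmua",
    "beer_lambert",
    "load_extinction_table",
]

DATA_TYPES = ("sdi25", "sdi37", "sdphi25", "sdphi37", "dsi", "dsphi")


@dataclass(frozen=True)
class DataTypeVector:
    """The six data types M of one DS set (one wavelength, one instant).

    sdi25/sdi37 are ln(rho^2 I) (natural-log units), sdphi25/sdphi37 phases
    in rad, dsi and dsphi the dual slopes in mm^-1 units.  ``se`` optionally
    carries a per-type standard error.
    """

    sdi25: float
    sdi37: float
    sdphi25: float
    sdphi37: float
    dsi: float
    dsphi: float
    rhos: tuple[float, float] = (25.0, 37.0)
    se: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in DATA_TYPES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, m) for m in DATA_TYPES])


def _ln_rho2_amp(value: complex, rho: float) -> float:
    amp = abs(value)
    if amp <= 0:
        raise ValueError("nonpositive reflectance amplitude")
    return float(np.log(rho * rho * amp))


def compute_datatypes(reflectances: dict, rhos: tuple[float, float] = (25.0, 37.0)) -> DataTypeVector:
    """Reduce the four channels of a DS set to the six data types.

    ``reflectances`` maps ``(source, detector)`` to a
    :class:`~layerlight.forward.ComplexReflectance` (or a bare complex,
    paired with the channel's rho via a 3-tuple key ``(source, detector,
    rho)``).  Exactly two channels per nominal distance are required — the
    mirror pairs — and are averaged at each rho.  Phases are unwrapped to the
    nearest branch within the set, valid while the 25-to-37 mm phase lag
    stays below pi (true for physiological properties at 140.625 MHz;
    asserted at runtime).
    """
    rho_s, rho_l = rhos
    per_source: dict = {}
    for key, r in reflectances.items():
        if isinstance(r, ComplexReflectance):
            src, rho, val = r.source, r.rho, r.value
            se_ln, se_ph = r.se_lnamp, r.se_phase
        else:
            src, _, rho = key
            val = complex(r)
            se_ln = se_ph = 0.0
        which = "short" if np.isclose(rho, rho_s) else "long" if np.isclose(rho, rho_l) else None
        if which is None:
            continue
        if which in per_source.setdefault(src, {}):
            raise ValueError(f"duplicate {which}-distance channel for source {src}")
        per_source[src][which] = (val, se_ln, se_ph)

    if len(per_source) != 2 or any(set(v) != {"short", "long"} for v in per_source.values()):
        raise ValueError(
            "a DS set needs two sources, each with one short- and one "
            f"long-distance channel; got {per_source}"
        )

    srcs = sorted(per_source)
    lnI = {}
    phase = {}
    se_lnI = {}
    se_phase = {}
    for s in srcs:
        (v_s, el_s, ep_s) = per_source[s]["short"]
        (v_l, el_l, ep_l) = per_source[s]["long"]
        lnI[(s, "short")] = _ln_rho2_amp(v_s, rho_s)
        lnI[(s, "long")] = _ln_rho2_amp(v_l, rho_l)
        p_s = float(np.angle(v_s))
        p_l = float(np.angle(v_l))
        # nearest-branch unwrapping within the set
        p_l += 2.0 * np.pi * np.round((p_s - p_l) / (2.0 * np.pi))
        if abs(p_l - p_s) >= np.pi:
            raise ValueError(
                "phase lag between the two distances exceeds pi; "
                "nearest-branch unwrapping is not valid here"
            )
        phase[(s, "short")] = p_s
        phase[(s, "long")] = p_l
        se_lnI[(s, "short")], se_lnI[(s, "long")] = el_s, el_l
        se_phase[(s, "short")], se_phase[(s, "long")] = ep_s, ep_l

    drho = rho_l - rho_s
    slopes_i = [(lnI[(s, "long")] - lnI[(s, "short")]) / drho for s in srcs]
    slopes_p = [(phase[(s, "long")] - phase[(s, "short")]) / drho for s in srcs]

    def _avg_se(d, which):
        return 0.5 * np.hypot(d[(srcs[0], which)], d[(srcs[1], which)])

    se = {
        "sdi25": _avg_se(se_lnI, "short"),
        "sdi37": _avg_se(se_lnI, "long"),
        "sdphi25": _avg_se(se_phase, "short"),
        "sdphi37": _avg_se(se_phase, "long"),
    }
    # DS slope = mean of the two per-source slopes, each slope a two-point
    # difference over drho
    se["dsi"] = 0.5 * np.hypot(
        np.hypot(se_lnI[(srcs[0], "short")], se_lnI[(srcs[0], "long")]),
        np.hypot(se_lnI[(srcs[1], "short")], se_lnI[(srcs[1], "long")]),
    ) / drho
    se["dsphi"] = 0.5 * np.hypot(
        np.hypot(se_phase[(srcs[0], "short")], se_phase[(srcs[0], "long")]),
        np.hypot(se_phase[(srcs[1], "short")], se_phase[(srcs[1], "long")]),
    ) / drho

    return DataTypeVector(
        sdi25=float(np.mean([lnI[(s, "short")] for s in srcs])),
        sdi37=float(np.mean([lnI[(s, "long")] for s in srcs])),
        sdphi25=float(np.mean([phase[(s, "short")] for s in srcs])),
        sdphi37=float(np.mean([phase[(s, "long")] for s in srcs])),
        dsi=float(np.mean(slopes_i)),
        dsphi=float(np.mean(slopes_p)),
        rhos=(float(rho_s), float(rho_l)),
        se=se,
    )


def delta_datatypes(base: DataTypeVector, perturbed: DataTypeVector) -> DataTypeVector:
    """Element-wise change Delta M = M_perturbed - M_base."""
    se = {
        m: float(np.hypot(base.se.get(m, 0.0), perturbed.se.get(m, 0.0)))
        for m in DATA_TYPES
        if base.se or perturbed.se
    }
    return DataTypeVector(
        *[getattr(perturbed, m) - getattr(base, m) for m in DATA_TYPES],
        rhos=base.rhos,
        se=se,
    )


@dataclass(frozen=True)
class AbsoluteProperties:
    """Effective homogeneous optical properties from the dual-slope fit."""

    mua: float
    musp: float
    converged: bool
    n_iterations: int
    residual: float
    wavelength: float | None = None


def _slope_model(mua, musp, omega, rhos, n_in, **kw):
    d = diffusion_datatypes(mua, musp, omega, rhos, n_in, **kw)
    return np.array([d["dsi"], d["dsphi"]])


def fit_absolute_properties(
    datatypes: DataTypeVector,
    omega: float = OMEGA_DEFAULT,
    n_in: float = 1.4,
    *,
    tol: float = 1e-9,
    max_iter: int = 100,
    wavelength: float | None = None,
    **model_kw,
) -> AbsoluteProperties:
    """Self-calibrated fit of (mua, mus') to the measured dual slopes.

    The initial guess inverts the infinite-medium relations
    ``k_r^2 - k_i^2 = 3 mua mus'`` and ``2 k_r k_i = 3 mus' omega n / c``
    with ``k_r ~ -dsi`` and ``k_i ~ dsphi``; a damped Newton iteration on the
    semi-infinite extrapolated-boundary model then matches the measured
    slopes until both residuals fall below ``tol`` (mm^-1) or ``max_iter`` is
    reached.  Non-convergence is flagged, never silent.
    """
    from .forward import C_MM_S

    dsi = datatypes.dsi
    dsphi = datatypes.dsphi
    if not dsi < 0:
        raise ValueError(f"dsi must be negative (decaying intensity), got {dsi}")
    if not dsphi > 0:
        raise ValueError(f"dsphi must be positive (growing phase lag), got {dsphi}")
    rhos = datatypes.rhos

    # infinite-medium closed-form guess
    k_r = -dsi
    k_i = dsphi
    musp0 = 2.0 * k_r * k_i * C_MM_S / (3.0 * omega * n_in)
    mua0 = (k_r * k_r - k_i * k_i) / (3.0 * musp0)
    if not np.isfinite(mua0) or mua0 <= 0:
        mua0 = 0.001
    if not np.isfinite(musp0) or musp0 <= 0:
        musp0 = 1.0

    target = np.array([dsi, dsphi])
    p = np.array([mua0, musp0])
    resid = _slope_model(p[0], p[1], omega, rhos, n_in, **model_kw) - target
    it = 0
    for it in range(1, max_iter + 1):
        if np.all(np.abs(resid) < tol):
            break
        # 2x2 Jacobian by forward differences
        J = np.empty((2, 2))
        for j in range(2):
            h = max(1e-7, 1e-6 * p[j])
            q = p.copy()
            q[j] += h
            J[:, j] = (_slope_model(q[0], q[1], omega, rhos, n_in, **model_kw)
                       - resid - target) / h
        try:
            dp = np.linalg.solve(J, -resid)
        except np.linalg.LinAlgError:
            break
        lam = 1.0
        best = np.sum(resid**2)
        for _ in range(25):
            q = p + lam * dp
            if q[0] <= 0 or q[1] <= 0:
                lam *= 0.5
                continue
            r_new = _slope_model(q[0], q[1], omega, rhos, n_in, **model_kw) - target
            if np.sum(r_new**2) < best:
                p, resid = q, r_new
                break
            lam *= 0.5
        else:
            break  # no productive step left
    converged = bool(np.all(np.abs(resid) < tol))
    return AbsoluteProperties(
        mua=float(p[0]),
        musp=float(p[1]),
        converged=converged,
        n_iterations=it,
        residual=float(np.max(np.abs(resid))),
        wavelength=wavelength,
    )


@dataclass(frozen=True)
class EffectiveAbsorptionChange:
    """Delta mua retrieved from one data type via its Jacobian."""

    data_type: str
    dmua: float
    standard_error: float = 0.0


def retrieve_dmua(delta_M: DataTypeVector, jacobians: dict) -> dict:
    """Effective absorption change per data type: Delta mua_M = Delta M / J_M.

    ``jacobians`` maps data-type name to dM/dmua (from
    :func:`~layerlight.forward.homogeneous_jacobian`, or the summed
    multi-layer derivative when analysing layered sensitivities).  Standard
    errors on Delta M, when present, scale by 1/|J|.
    """
    out = {}
    for m in DATA_TYPES:
        J = jacobians[m]
        if J == 0 or not np.isfinite(J):
            raise ValueError(f"degenerate Jacobian for data type {m}")
        dM = getattr(delta_M, m)
        out[m] = EffectiveAbsorptionChange(
            data_type=m,
            dmua=float(dM / J),
            standard_error=float(delta_M.se.get(m, 0.0) / abs(J)),
        )
    return out


# ---------------------------------------------------------------------------
# Beer's law
# ---------------------------------------------------------------------------

def load_extinction_table() -> dict:
    """Molar extinction coefficients of HbO2 and Hb (cm^-1 / M).

    Values from the Prahl compilation of hemoglobin spectra, shipped as a
    small CSV; override by passing an explicit table to
    :func:`beer_lambert`.
    """
    ref = resources.files("layerlight").joinpath("data/extinction_hb.csv")
    table = {}
    with ref.open() as fh:
        header = fh.readline()
        assert "wavelength" in header
        for line in fh:
            lam, e_hbo2, e_hb = line.split(",")
            table[float(lam)] = (float(e_hbo2), float(e_hb))
    return table


def beer_lambert(
    dmua_690: float,
    dmua_830: float,
    extinction_table: dict | None = None,
    wavelengths: tuple[float, float] = (690.0, 830.0),
) -> tuple[float, float]:
    """Solve Beer's law for (Delta[HbO2], Delta[Hb]) in micromolar.

    Delta mua(lambda) = ln(10) * [eps_HbO2(lambda) dHbO2 + eps_Hb(lambda) dHb]
    with eps in cm^-1/M and concentrations in uM (the 10^-7 factor converts
    cm^-1/M * uM to mm^-1).
    """
    table = extinction_table or load_extinction_table()
    try:
        eps = np.array([table[w] for w in wavelengths], float)
    except KeyError as e:
        raise KeyError(f"extinction table lacks wavelength {e}") from None
    A = np.log(10.0) * eps * 1e-7  # mm^-1 per uM
    if abs(np.linalg.det(A)) < 1e-18:
        raise ValueError("singular extinction matrix: wavelengths not independent")
    sol = np.linalg.solve(A, np.array([dmua_690, dmua_830]))
    return float(sol[0]), float(sol[1])
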