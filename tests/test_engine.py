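import numpy as np
import pytest

from layerlight.engine import (
    DATA_TYPES,
    DataTypeVector,
    beer_lambert,
    compute_datatypes,
    delta_datatypes,
    fit_absolute_properties,
    load_extinction_table,
    retrieve_dmua,
)
from layerlight.forward import diffusion_datatypes, diffusion_reflectance, homogeneous_jacobian


def analytic_channels(mua, musp, rhos=(25.0, 37.0), **kw):
    """Four-channel DS set built from the homogeneous diffusion model."""
    r_s, r_l = rhos
    v_s = complex(diffusion_reflectance(r_s, mua, musp, **kw))
    v_l = complex(diffusion_reflectance(r_l, mua, musp, **kw))
    return {
        (0, 0, r_s): v_s,
        (0, 1, r_l): v_l,
        (1, 1, r_s): v_s,
        (1, 0, r_l): v_l,
    }


class TestComputeDatatypes:
    def test_analytic_slope_signs(self):
        dtv = compute_datatypes(analytic_channels(0.01, 1.0))
        assert dtv.dsi < 0 and dtv.dsphi > 0

    def test_matches_diffusion_datatypes(self):
        dtv = compute_datatypes(analytic_channels(0.01, 1.0))
        ref = diffusion_datatypes(0.01, 1.0)
        for m in DATA_TYPES:
            assert getattr(dtv, m) == pytest.approx(ref[m], rel=1e-12)

    def test_self_calibration_coupling_invariance(self):
        ch = analytic_channels(0.013, 0.9)
        coupled = dict(ch)
        factor_det1 = 3.0 * np.exp(1j * 0.2)
        factor_srcB = 0.45 * np.exp(-1j * 1.1)
        for (src, det, rho) in list(coupled):
            v = coupled[(src, det, rho)]
            if det == 1:
                v = v * factor_det1
            if src == 1:
                v = v * factor_srcB
            coupled[(src, det, rho)] = v
        a = compute_datatypes(ch)
        b = compute_datatypes(coupled)
        assert b.dsi == pytest.approx(a.dsi, rel=1e-13)
        assert b.dsphi == pytest.approx(a.dsphi, rel=1e-13)
        # single-distance types are NOT coupling-invariant
        assert not np.isclose(b.sdi25, a.sdi25)

    def test_ds_slope_is_mean_of_single_slopes(self):
        # asymmetric mirror channels: the DS slope must still equal the mean
        ch = analytic_channels(0.01, 1.0)
        ch[(1, 1, 25.0)] *= 1.5  # de-symmetrize source B
        dtv = compute_datatypes(ch)
        lnI = {k: np.log(rho**2 * abs(v)) for (s, d, rho), v in ch.items() for k in [(s, rho)]}
        slope_a = (lnI[(0, 37.0)] - lnI[(0, 25.0)]) / 12.0
        slope_b = (lnI[(1, 37.0)] - lnI[(1, 25.0)]) / 12.0
        assert dtv.dsi == pytest.approx(0.5 * (slope_a + slope_b), rel=1e-12)

    def test_mirror_symmetric_inputs_slope_equals_either_source(self):
        dtv = compute_datatypes(analytic_channels(0.01, 1.0))
        ref = diffusion_datatypes(0.01, 1.0)
        assert dtv.dsi == pytest.approx(ref["dsi"], rel=1e-12)

    def test_missing_channel_rejected(self):
        ch = analytic_channels(0.01, 1.0)
        ch.pop((1, 0, 37.0))
        with pytest.raises(ValueError):
            compute_datatypes(ch)

    def test_zero_amplitude_rejected(self):
        ch = analytic_channels(0.01, 1.0)
        ch[(0, 0, 25.0)] = 0.0
        with pytest.raises(ValueError):
            compute_datatypes(ch)


class TestFitAbsoluteProperties:
    def test_round_trip_single_point(self):
        dtv = compute_datatypes(analytic_channels(0.01, 1.0))
        props = fit_absolute_properties(dtv)
        assert props.converged
        assert props.mua == pytest.approx(0.01, rel=1e-3)
        assert props.musp == pytest.approx(1.0, rel=1e-3)

    def test_round_trip_grid(self):
        for mua in (0.005, 0.012, 0.025):
            for musp in (0.4, 1.0, 1.8):
                dtv = compute_datatypes(analytic_channels(mua, musp))
                props = fit_absolute_properties(dtv)
                assert props.converged, (mua, musp)
                assert props.mua == pytest.approx(mua, rel=1e-3), (mua, musp)
                assert props.musp == pytest.approx(musp, rel=1e-3), (mua, musp)

    def test_wrong_sign_slopes_rejected(self):
        dtv = DataTypeVector(0, 0, 0, 0, dsi=+0.1, dsphi=0.02)
        with pytest.raises(ValueError):
            fit_absolute_properties(dtv)
        dtv = DataTypeVector(0, 0, 0, 0, dsi=-0.1, dsphi=-0.02)
        with pytest.raises(ValueError):
            fit_absolute_properties(dtv)


class TestRetrieveDmua:
    def test_zero_change_maps_to_zero(self):
        jac = homogeneous_jacobian(0.01, 1.0)
        zero = DataTypeVector(0, 0, 0, 0, 0, 0)
        out = retrieve_dmua(zero, jac)
        assert all(out[m].dmua == 0.0 for m in DATA_TYPES)

    def test_retrieval_linearity(self):
        base = diffusion_datatypes(0.01, 1.0)
        jac = homogeneous_jacobian(0.01, 1.0)
        # the retrieval is a linearization: its error grows with amplitude
        for true_dmua, tol in ((1e-4, 0.01), (5e-4, 0.04), (1e-3, 0.08)):
            pert = diffusion_datatypes(0.01 + true_dmua, 1.0)
            delta = DataTypeVector(*[pert[m] - base[m] for m in DATA_TYPES])
            out = retrieve_dmua(delta, jac)
            for m in DATA_TYPES:
                assert out[m].dmua == pytest.approx(true_dmua, rel=tol), (m, true_dmua)

    def test_zero_jacobian_rejected(self):
        jac = homogeneous_jacobian(0.01, 1.0)
        jac["dsi"] = 0.0
        delta = DataTypeVector(0, 0, 0, 0, 0, 0)
        with pytest.raises(ValueError):
            retrieve_dmua(delta, jac)

    def test_standard_error_scaling(self):
        jac = homogeneous_jacobian(0.01, 1.0)
        delta = DataTypeVector(0, 0, 0, 0, 0, 0, se={m: 1e-3 for m in DATA_TYPES})
        out = retrieve_dmua(delta, jac)
        for m in DATA_TYPES:
            assert out[m].standard_error == pytest.approx(1e-3 / abs(jac[m]))


class TestDeltaDatatypes:
    def test_elementwise_difference(self):
        a = DataTypeVector(1, 2, 3, 4, 5, 6)
        b = DataTypeVector(2, 4, 6, 8, 10, 12)
        d = delta_datatypes(a, b)
        assert d.as_array() == pytest.approx([1, 2, 3, 4, 5, 6])


class TestBeerLambert:
    def test_zero_maps_to_zero(self):
        assert beer_lambert(0.0, 0.0) == (0.0, 0.0)

    def test_round_trip(self):
        table = load_extinction_table()
        eps = np.array([table[690.0], table[830.0]])
        A = np.log(10.0) * eps * 1e-7
        d690, d830 = A @ np.array([1.0, -0.3])
        hbo2, hb = beer_lambert(d690, d830)
        assert hbo2 == pytest.approx(1.0, rel=1e-12)
        assert hb == pytest.approx(-0.3, rel=1e-12)

    def test_functional_sign_structure(self):
        # strong 830 nm absorption increase, flat 690 nm -> HbO2 up, Hb down
        hbo2, hb = beer_lambert(0.0, 1e-4)
        assert hbo2 > 0 and hb < 0

    def test_singular_table_rejected(self):
        table = {690.0: (100.0, 200.0), 830.0: (100.0, 200.0)}
        with pytest.raises(ValueError):
            beer_lambert(1e-4, 1e-4, extinction_table=table)

    def test_missing_wavelength_rejected(self):
        with pytest.raises(KeyError):
            beer_lambert(1e-4, 1e-4, wavelengths=(690.0, 800.0))

    def test_shipped_table_wavelengths(self):
        table = load_extinction_table()
        for w in (660.0, 690.0, 750.0, 830.0):
            assert w in table
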