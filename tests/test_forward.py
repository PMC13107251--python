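import numpy as np
import pytest

from layerlight.forward import (
    C_MM_S,
    OMEGA_DEFAULT,
    assemble_reflectance,
    diffusion_datatypes,
    diffusion_reflectance,
    homogeneous_jacobian,
    layer_derivatives,
    perturbed_reflectance,
    reff_fresnel,
    reflectance_to_frame,
)
from layerlight.mc import PathLedger, run_white_mc
from layerlight.media import make_homogeneous


def tiny_ledger(paths, n_launched=1, area=1.0, nl=None):
    """Hand-built single-channel ledger for closed-form checks."""
    paths = np.atleast_2d(np.asarray(paths, float))
    nl = nl or paths.shape[1]
    n = paths.shape[0]
    return PathLedger(
        paths=paths,
        source=np.zeros(n, dtype=np.int64),
        detector=np.zeros(n, dtype=np.int64),
        n_launched=np.array([n_launched], dtype=np.int64),
        detector_area=np.array([area]),
        rho={(0, 0): 25.0},
        layer_n=np.full(nl, 1.4),
        tally_mode="annular",
        seed=0,
        max_path=2000.0,
    )


class TestAssembleReflectance:
    def test_zero_absorption_dc_counts_over_norm(self):
        led = tiny_ledger([[10.0], [20.0], [5.0]], n_launched=100, area=2.0)
        refl = assemble_reflectance(led, [0.0], omega=0.0)
        r = refl[(0, 0)]
        assert r.value == pytest.approx(3 / (100 * 2.0))
        assert r.value.imag == 0.0

    def test_single_photon_closed_form(self):
        led = tiny_ledger([[10.0]])
        r = assemble_reflectance(led, [0.1], omega=0.0)[(0, 0)]
        assert r.value.real == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_single_photon_phase_factor(self):
        led = tiny_ledger([[10.0]])
        r = assemble_reflectance(led, [0.0], omega=OMEGA_DEFAULT)[(0, 0)]
        expected_phase = OMEGA_DEFAULT * 10.0 * 1.4 / C_MM_S
        assert np.angle(r.value) == pytest.approx(expected_phase, rel=1e-12)
        assert abs(r.value) == pytest.approx(1.0, rel=1e-12)

    def test_empty_ledger_rejected(self):
        led = tiny_ledger(np.zeros((0, 1)))
        with pytest.raises(ValueError):
            assemble_reflectance(led, [0.01])

    def test_negative_mua_rejected(self):
        with pytest.raises(ValueError):
            assemble_reflectance(tiny_ledger([[10.0]]), [-0.01])

    def test_wrong_mua_length_rejected(self):
        with pytest.raises(ValueError):
            assemble_reflectance(tiny_ledger([[10.0]]), [0.01, 0.02])


class TestPerturbedReflectance:
    def test_zero_delta_identity(self, small_three_layer_ledger):
        base, pert = perturbed_reflectance(
            small_three_layer_ledger, [0.017, 0.0027, 0.021], [0.0, 0.0, 0.0]
        )
        for key in base:
            assert base[key].value == pert[key].value

    def test_deep_absorption_increase_reduces_amplitude(self, small_three_layer_ledger):
        base, pert = perturbed_reflectance(
            small_three_layer_ledger, [0.017, 0.0027, 0.021], [0.0, 0.0, 0.001]
        )
        for key in base:
            assert abs(pert[key].value) < abs(base[key].value)

    def test_unvisited_layer_changes_nothing(self):
        led = tiny_ledger([[10.0, 0.0], [25.0, 0.0]], n_launched=10, nl=2)
        base, pert = perturbed_reflectance(led, [0.01, 0.02], [0.0, 0.5])
        assert base[(0, 0)].value == pert[(0, 0)].value

    def test_correlated_difference_beats_independent_ledgers(self, optodes):
        medium = make_homogeneous(0.01, 1.0)
        mua = np.array([0.01])
        delta = np.array([0.001])
        diffs_corr, diffs_indep = [], []
        for seed in range(6):
            la = run_white_mc(medium, optodes, 50_000, seed=100 + seed)
            lb = run_white_mc(medium, optodes, 50_000, seed=200 + seed)
            b, p = perturbed_reflectance(la, mua, delta)
            diffs_corr.append(p[(0, 1)].value - b[(0, 1)].value)
            b2 = assemble_reflectance(lb, mua + delta)
            diffs_indep.append(b2[(0, 1)].value - b[(0, 1)].value)
        var_corr = np.var(np.real(diffs_corr))
        var_indep = np.var(np.real(diffs_indep))
        assert var_corr < var_indep


class TestLayerDerivatives:
    def test_single_photon_closed_form(self):
        led = tiny_ledger([[10.0]])
        d = layer_derivatives(led, [0.0], omega=0.0)[(0, 0)]
        assert d.dR_dmua[0] == pytest.approx(-10.0, rel=1e-12)

    def test_matches_central_finite_difference(self, small_three_layer_ledger):
        mua = np.array([0.017, 0.0027, 0.021])
        derivs = layer_derivatives(small_three_layer_ledger, mua)
        h = 1e-6
        for j in range(3):
            up = mua.copy(); up[j] += h
            lo = mua.copy(); lo[j] -= h
            ru = assemble_reflectance(small_three_layer_ledger, up)
            rl = assemble_reflectance(small_three_layer_ledger, lo)
            for key, d in derivs.items():
                fd = (ru[key].value - rl[key].value) / (2 * h)
                assert abs(d.dR_dmua[j] - fd) <= 1e-6 * abs(fd)

    def test_layer_additivity_equals_total_path_derivative(self):
        led = tiny_ledger([[4.0, 3.0, 2.0], [1.0, 0.5, 0.1]], n_launched=7, nl=3)
        mua = np.array([0.01, 0.002, 0.02])
        d = layer_derivatives(led, mua, omega=0.0)[(0, 0)]
        w = np.exp(-led.paths @ mua)
        expected_total = -(led.paths.sum(axis=1) * w).sum() / 7.0
        assert d.dR_dmua.sum().real == pytest.approx(expected_total, rel=1e-12)


class TestDiffusionModel:
    def test_reff_for_tissue_air(self):
        assert reff_fresnel(1.4) == pytest.approx(0.493, abs=0.01)
        assert reff_fresnel(1.0) == 0.0

    def test_dc_limit_is_real(self):
        r = diffusion_reflectance(25.0, 0.01, 1.0, omega=0.0)
        assert np.imag(r) == 0.0 and np.real(r) > 0

    def test_amplitude_decreases_with_rho_and_mua(self):
        rho = np.linspace(15.0, 45.0, 10)
        amp = np.abs(diffusion_reflectance(rho, 0.01, 1.0))
        assert np.all(np.diff(amp) < 0)
        a1 = np.abs(diffusion_reflectance(25.0, 0.01, 1.0))
        a2 = np.abs(diffusion_reflectance(25.0, 0.02, 1.0))
        assert a2 < a1

    def test_phase_monotonically_increases_with_rho(self):
        for mua in (0.005, 0.01, 0.025):
            for musp in (0.4, 1.0, 1.8):
                rho = np.linspace(20.0, 40.0, 9)
                ph = np.unwrap(np.angle(diffusion_reflectance(rho, mua, musp)))
                assert np.all(np.diff(ph) > 0), (mua, musp)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            diffusion_reflectance(-1.0, 0.01, 1.0)
        with pytest.raises(ValueError):
            diffusion_reflectance(25.0, 0.01, -1.0)
        with pytest.raises(ValueError):
            diffusion_reflectance(25.0, 0.01, 1.0, d_mode="bogus")

    def test_datatype_slope_signs(self):
        d = diffusion_datatypes(0.01, 1.0)
        assert d["dsi"] < 0 and d["dsphi"] > 0


class TestHomogeneousJacobian:
    def test_slope_jacobian_is_linear_combination(self):
        jac = homogeneous_jacobian(0.01, 1.0)
        assert jac["dsi"] == pytest.approx((jac["sdi37"] - jac["sdi25"]) / 12.0, rel=1e-9)
        assert jac["dsphi"] == pytest.approx((jac["sdphi37"] - jac["sdphi25"]) / 12.0, rel=1e-9)

    def test_step_halving_stability(self):
        j1 = homogeneous_jacobian(0.01, 1.0, step=1e-5)
        j2 = homogeneous_jacobian(0.01, 1.0, step=5e-6)
        for m in j1:
            assert abs(j1[m] - j2[m]) <= 1e-4 * abs(j1[m])

    def test_intensity_jacobians_negative(self):
        jac = homogeneous_jacobian(0.01, 1.0)
        assert jac["sdi25"] < 0 and jac["sdi37"] < 0 and jac["dsi"] < 0

    def test_equal_distances_rejected(self):
        with pytest.raises(ValueError):
            homogeneous_jacobian(0.01, 1.0, rhos=(25.0, 25.0))


def test_reflectance_frame_schema(small_three_layer_ledger):
    refl = assemble_reflectance(small_three_layer_ledger, [0.017, 0.0027, 0.021])
    frame = reflectance_to_frame(refl)
    assert list(frame.columns) == [
        "source", "detector", "rho_mm", "amplitude", "phase_rad",
        "se_amp", "se_phase", "omega_rad_s", "wavelength_nm",
    ]
    assert len(frame) == 4
    assert (frame["amplitude"] > 0).all()
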