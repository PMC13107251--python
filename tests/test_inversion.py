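import numpy as np
import pytest

from layerlight.engine import DATA_TYPES, compute_datatypes, delta_datatypes, retrieve_dmua
from layerlight.forward import (
    assemble_reflectance,
    homogeneous_jacobian,
    layer_derivatives,
)
from layerlight.inversion import (
    build_sensitivity_matrix,
    datatype_layer_derivatives,
    propagate_sem,
    solve_layers,
)


@pytest.fixture(scope="module")
def three_layer_sensitivity(small_three_layer_ledger):
    mua = np.array([0.017, 0.0027, 0.021])
    derivs = layer_derivatives(small_three_layer_ledger, mua)
    return build_sensitivity_matrix(derivs)


class TestSensitivityMatrix:
    def test_shape_and_rank(self, three_layer_sensitivity):
        S = three_layer_sensitivity
        assert S.S.shape == (6, 2)
        assert S.rank == 2
        assert np.isfinite(S.condition_number)

    def test_fractions_rows_sum_to_one(self, three_layer_sensitivity):
        sums = three_layer_sensitivity.fractions.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_pseudoinverse_left_identity(self, three_layer_sensitivity):
        S = three_layer_sensitivity.S
        assert np.allclose(np.linalg.pinv(S) @ S, np.eye(2), atol=1e-10)

    def test_csf_column_excluded(self, three_layer_sensitivity):
        assert three_layer_sensitivity.retained_layers == (0, 2)

    def test_json_round_trip(self, tmp_path, three_layer_sensitivity):
        import json

        path = tmp_path / "sens.json"
        three_layer_sensitivity.to_json(path)
        doc = json.loads(path.read_text())
        assert np.allclose(doc["S"], three_layer_sensitivity.S)
        assert doc["data_types"] == list(DATA_TYPES)


class TestLayerDerivativeRows:
    def test_row_sums_equal_uniform_absorption_derivative(self, small_three_layer_ledger):
        """Raising every layer's mua equally must equal the summed row (chain rule)."""
        mua = np.array([0.017, 0.0027, 0.021])
        rows = datatype_layer_derivatives(layer_derivatives(small_three_layer_ledger, mua))
        h = 1e-6
        up = compute_datatypes(assemble_reflectance(small_three_layer_ledger, mua + h))
        lo = compute_datatypes(assemble_reflectance(small_three_layer_ledger, mua - h))
        fd = (up.as_array() - lo.as_array()) / (2 * h)
        assert np.allclose(rows.sum(axis=1), fd, rtol=1e-6)

    def test_dual_slope_rows_near_homogeneous_jacobian(self, small_homogeneous_ledger):
        """On a homogeneous ledger the summed derivative should approximate the
        analytic homogeneous Jacobian (MC noise + diffusion-model allowance)."""
        rows = datatype_layer_derivatives(layer_derivatives(small_homogeneous_ledger, [0.01]))
        jac = homogeneous_jacobian(0.01, 1.0)
        for i, m in enumerate(("dsi", "dsphi")):
            mc = rows[4 + i, 0]
            assert mc == pytest.approx(jac[m], rel=0.15), m

    def test_incomplete_channel_set_rejected(self, small_three_layer_ledger):
        mua = np.array([0.017, 0.0027, 0.021])
        derivs = layer_derivatives(small_three_layer_ledger, mua)
        derivs.pop((0, 0))
        with pytest.raises(ValueError):
            datatype_layer_derivatives(derivs)


class TestSolveLayers:
    def test_exact_recovery_consistent_system(self, three_layer_sensitivity):
        planted = np.array([2e-4, 1.5e-3])
        vec = three_layer_sensitivity.S @ planted
        sol = solve_layers(vec, three_layer_sensitivity)
        assert sol.dmua_layer1 == pytest.approx(planted[0], rel=1e-10)
        assert sol.dmua_layer3 == pytest.approx(planted[1], rel=1e-10)
        assert sol.residual_norm < 1e-15

    def test_unbiased_under_noise(self, three_layer_sensitivity):
        rng = np.random.default_rng(7)
        planted = np.array([0.0, 1e-3])
        clean = three_layer_sensitivity.S @ planted
        l1 = []
        for _ in range(200):
            sol = solve_layers(clean + rng.normal(0, 1e-5, 6), three_layer_sensitivity)
            l1.append(sol.dmua_layer1)
        sem = np.std(l1, ddof=1) / np.sqrt(len(l1))
        assert abs(np.mean(l1)) < 3 * sem

    def test_accepts_retrieve_dmua_output(self, small_three_layer_ledger, three_layer_sensitivity):
        mua = np.array([0.017, 0.0027, 0.021])
        base = compute_datatypes(assemble_reflectance(small_three_layer_ledger, mua))
        pert = compute_datatypes(
            assemble_reflectance(small_three_layer_ledger, mua + [0.0, 0.0, 1e-3])
        )
        dM = delta_datatypes(base, pert)
        dmua = retrieve_dmua(dM, three_layer_sensitivity.summed_jacobian)
        sol = solve_layers(dmua, three_layer_sensitivity)
        assert np.isfinite(sol.dmua_layer1) and np.isfinite(sol.dmua_layer3)
        assert sol.sem_layer1 >= 0 and sol.sem_layer3 >= 0

    def test_rank_deficient_rejected(self):
        S = np.ones((6, 2))
        with pytest.raises(ValueError):
            solve_layers(np.zeros(6), S)

    def test_wrong_length_vector_rejected(self, three_layer_sensitivity):
        with pytest.raises(ValueError):
            solve_layers(np.zeros(5), three_layer_sensitivity)


class TestPropagateSem:
    def test_zero_sems(self, three_layer_sensitivity):
        out = propagate_sem(three_layer_sensitivity, np.zeros(6))
        assert out == (0.0, 0.0)

    def test_single_nonzero_entry(self, three_layer_sensitivity):
        pinv = np.linalg.pinv(three_layer_sensitivity.S)
        sem = np.zeros(6)
        sem[3] = 2e-4
        out = propagate_sem(three_layer_sensitivity, sem)
        assert out[0] == pytest.approx(abs(pinv[0, 3]) * 2e-4, rel=1e-12)
        assert out[1] == pytest.approx(abs(pinv[1, 3]) * 2e-4, rel=1e-12)

    def test_equal_sems_closed_form(self, three_layer_sensitivity):
        pinv = np.linalg.pinv(three_layer_sensitivity.S)
        s = 3e-5
        out = propagate_sem(three_layer_sensitivity, np.full(6, s))
        assert out[0] == pytest.approx(s * np.linalg.norm(pinv[0]), rel=1e-12)
        assert out[1] == pytest.approx(s * np.linalg.norm(pinv[1]), rel=1e-12)

    def test_negative_sem_rejected(self, three_layer_sensitivity):
        with pytest.raises(ValueError):
            propagate_sem(three_layer_sensitivity, [-1.0, 0, 0, 0, 0, 0])
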