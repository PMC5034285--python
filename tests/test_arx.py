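"""ARX identification: design matrix, fitting, free-run prediction, R2."""

import numpy as np
import pytest

from larvavr import (
    ARXConfig,
    ARXModel,
    bootstrap_evaluate,
    build_design_matrix,
    cross_amplitude_evaluate,
    fit,
    goodness_of_fit,
    make_library,
    one_step_predict,
    predict,
)
from larvavr.arx import TARGETS, fit_bouts
from larvavr.config import default_arx_configs
from larvavr.synth import noise_sd_for_output_ratio, random_stable_model


class TestDesignMatrix:
    def test_shape_arithmetic(self):
        y = np.arange(10.0)
        x = np.ones(10)
        phi, target = build_design_matrix(y, x, ARXConfig(2, 1))
        assert phi.shape == (10, 4)
        np.testing.assert_array_equal(target, y)

    def test_first_row_is_rest(self):
        y = np.arange(1.0, 11.0)
        x = np.arange(10.0) + 5.0
        phi, _ = build_design_matrix(y, x, ARXConfig(2, 1))
        # at k=0 only the b_0 * x(0) column is nonzero
        np.testing.assert_array_equal(phi[0], [0.0, 0.0, x[0], 0.0])

    def test_rows_match_hand_written_loop(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=6)
        x = rng.normal(size=6)
        cfg = ARXConfig(2, 2)
        phi, _ = build_design_matrix(y, x, cfg)
        for k in range(6):
            row = []
            for i in range(1, 3):
                row.append(-y[k - i] if k - i >= 0 else 0.0)
            for j in range(3):
                row.append(x[k - j] if k - j >= 0 else 0.0)
            np.testing.assert_allclose(phi[k], row, atol=1e-15)

    def test_absolute_value_transform_applied(self):
        y = np.zeros(5)
        x = np.array([-1.0, 2.0, -3.0, 4.0, -5.0])
        phi, _ = build_design_matrix(y, x, ARXConfig(1, 0, "absolute_value"))
        np.testing.assert_array_equal(phi[:, 1], np.abs(x))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            build_design_matrix(np.ones(5), np.ones(5), ARXConfig(3, 2))


class TestFit:
    def test_noiseless_recovery_of_known_coefficients(self):
        cfg = ARXConfig(2, 1)
        true = ARXModel(cfg, [-0.6, 0.08], [1.0, 0.5], "lateral_speed")
        rng = np.random.default_rng(0)
        x = rng.normal(size=501)
        y = predict(true, x)
        m = fit(y, x, cfg)
        np.testing.assert_allclose(m.theta, true.theta, atol=1e-8)

    def test_identity_system(self):
        x = np.random.default_rng(1).normal(size=100)
        m = fit(x.copy(), x, ARXConfig(1, 0))
        assert m.b[0] == pytest.approx(1.0, abs=1e-10)
        assert m.a[0] == pytest.approx(0.0, abs=1e-10)

    def test_noisy_recovery_within_three_standard_errors(self):
        """Equation noise: each coefficient within 3 analytic OLS SEs."""
        cfg = ARXConfig(2, 1)
        true = ARXModel(cfg, [-0.6, 0.08], [1.0, 0.5], "lateral_speed")
        rng = np.random.default_rng(3)
        x = rng.normal(size=5001)
        y_clean = predict(true, x)
        sd = 0.1 * y_clean.std()
        # equation noise fed through the AR part
        e = rng.normal(0, sd, len(x))
        y = np.empty(len(x))
        for k in range(len(x)):
            acc = e[k]
            for j in range(min(1, k) + 1):
                acc += true.b[j] * x[k - j]
            for i in range(1, min(2, k) + 1):
                acc -= true.a[i - 1] * y[k - i]
            y[k] = acc
        m = fit(y, x, cfg)
        phi, _ = build_design_matrix(y, x, cfg)
        resid = y - phi @ m.theta
        sigma2 = resid @ resid / (len(y) - len(m.theta))
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(phi.T @ phi)))
        assert np.all(np.abs(m.theta - true.theta) < 3 * se)

    def test_all_zero_system_returns_zero_theta(self, caplog):
        with caplog.at_level("WARNING", logger="larvavr"):
            m = fit(np.zeros(50), np.zeros(50), ARXConfig(2, 1))
        assert not m.theta.any()
        assert any("degenerate" in msg for msg in caplog.messages)

    @pytest.mark.parametrize("target", TARGETS)
    def test_property_exact_recovery_of_random_stable_models(self, target):
        """Noiseless simulate->fit recovers any stable coefficient set."""
        cfgs = default_arx_configs()
        rng = np.random.default_rng(hash(target) % 2**31)
        for _ in range(10):
            true = random_stable_model(cfgs[target], rng, target)
            x = rng.normal(size=2000)
            y = predict(true, x)
            m = fit(y, x, cfgs[target], target)
            np.testing.assert_allclose(m.theta, true.theta, atol=1e-8)


class TestPredict:
    def test_zero_input_zero_output(self, true_models):
        for t in TARGETS:
            assert not predict(true_models[t], np.zeros(50)).any()

    def test_oracle_round_trip_on_training_input(self):
        cfg = ARXConfig(2, 1)
        true = ARXModel(cfg, [-0.6, 0.08], [1.0, 0.5], "yaw_speed")
        x = np.random.default_rng(4).normal(size=400)
        y = predict(true, x)
        m = fit(y, x, cfg)
        np.testing.assert_allclose(predict(m, x), y, atol=1e-6)

    def test_geometric_impulse_response(self):
        m = ARXModel(ARXConfig(1, 0), [-0.5], [1.0], "axial_speed")
        x = np.zeros(6)
        x[0] = 1.0
        np.testing.assert_allclose(predict(m, x), 0.5 ** np.arange(6), atol=1e-12)

    def test_history_initialization(self):
        m = ARXModel(ARXConfig(1, 0), [-0.5], [0.0], "axial_speed")
        y = predict(m, np.zeros(4), y_history=[2.0])
        np.testing.assert_allclose(y, [1.0, 0.5, 0.25, 0.125])

    def test_divergence_names_the_frame(self):
        m = ARXModel(ARXConfig(1, 0), [-2.0], [1.0], "axial_speed")
        x = np.zeros(100)
        x[0] = 1.0
        with pytest.raises(FloatingPointError, match="frame"):
            predict(m, x)

    def test_teacher_forced_residuals_equal_least_squares_residuals(self):
        rng = np.random.default_rng(5)
        cfg = ARXConfig(3, 2)
        x = rng.normal(size=300)
        y = rng.normal(size=300)
        m = fit(y, x, cfg)
        phi, _ = build_design_matrix(y, x, cfg)
        np.testing.assert_allclose(y - one_step_predict(m, y, x),
                                   y - phi @ m.theta, atol=1e-12)

    def test_absolute_input_symmetry(self, true_models):
        """Axial (|x| input) is even in x; lateral/yaw (identity) are odd."""
        x = np.random.default_rng(6).normal(size=200)
        ax1 = predict(true_models["axial_speed"], x)
        ax2 = predict(true_models["axial_speed"], -x)
        np.testing.assert_allclose(ax1, ax2, atol=1e-12)
        for t in ("lateral_speed", "yaw_speed"):
            np.testing.assert_allclose(
                predict(true_models[t], -x), -predict(true_models[t], x), atol=1e-12
            )


class TestGoodnessOfFit:
    def test_perfect_and_mean_predictions(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert goodness_of_fit(y, y) == 1.0
        assert goodness_of_fit(y, np.full(4, y.mean())) == 0.0

    def test_hand_computed_example(self):
        assert goodness_of_fit([1, 2, 3, 4], [1, 2, 3, 5]) == pytest.approx(0.8)

    def test_affine_invariance(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=50)
        yhat = y + rng.normal(0, 0.3, 50)
        r2 = goodness_of_fit(y, yhat)
        assert goodness_of_fit(3.2 * y - 1.5, 3.2 * yhat - 1.5) == pytest.approx(r2)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            goodness_of_fit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestBootstrapEvaluate:
    def test_noiseless_library_self_consistency(self, clean_library):
        res = bootstrap_evaluate(clean_library, n_iter=3, seed=0)
        for t in TARGETS:
            assert res[t]["mean"] > 0.999

    def test_single_iteration_reproducible(self, clean_library):
        a = bootstrap_evaluate(clean_library, n_iter=1, seed=11)
        b = bootstrap_evaluate(clean_library, n_iter=1, seed=11)
        for t in TARGETS:
            assert a[t]["mean"] == b[t]["mean"]

    def test_controlled_noise_matches_variance_ratio(self, true_models):
        """Output noise at 1/3 of the signal variance caps pooled R2 at
        var(signal)/var(signal+noise) = 0.75."""
        clean = make_library(120, models=true_models, seed=11)
        sds = noise_sd_for_output_ratio(true_models, clean, 1.0 / 3.0)
        noisy = make_library(120, models=true_models, noise_sd=sds, seed=11)
        res = bootstrap_evaluate(noisy, n_iter=10, seed=1)
        for t in TARGETS:
            assert res[t]["mean"] == pytest.approx(0.75, abs=0.05)

    def test_invalid_arguments(self, clean_library):
        with pytest.raises(ValueError, match="n_iter"):
            bootstrap_evaluate(clean_library, n_iter=0)
        tiny = make_library(3, seed=0)
        with pytest.raises(ValueError, match="5 bouts"):
            bootstrap_evaluate(tiny)


class TestCrossAmplitudeEvaluate:
    def test_noiseless_self_consistency(self, clean_library):
        res = cross_amplitude_evaluate(clean_library)
        for direction in res.values():
            for t in TARGETS:
                assert direction[t] > 0.999

    def test_four_bouts_split_two_two(self, true_models):
        lib = make_library(4, models=true_models, seed=9)
        res = cross_amplitude_evaluate(lib)
        assert set(res) == {"train_small_test_large", "train_large_test_small"}

    def test_amplitude_dependent_noise_splits_the_axial_cells(self, true_models):
        """Extra axial noise confined to small bouts separates the two
        axial generalization cells while lateral/yaw stay clean."""
        lib = make_library(60, models=true_models, seed=21)
        amps = np.array([e.max_abs_deflection for e in lib.entries])
        order = np.argsort(amps, kind="stable")
        rng = np.random.default_rng(5)
        for i in order[: len(order) // 2]:
            e = lib.entries[i]
            sd = e.kinematics.axial_speed.std()
            e.kinematics.axial_speed = e.kinematics.axial_speed + rng.normal(
                0, sd, len(e.kinematics)
            )
        res = cross_amplitude_evaluate(lib)
        ax_sl = res["train_small_test_large"]["axial_speed"]
        ax_ls = res["train_large_test_small"]["axial_speed"]
        assert abs(ax_sl - ax_ls) > 0.2  # the noisy half caps whoever tests on it
        for direction in res.values():
            for t in ("lateral_speed", "yaw_speed"):
                assert direction[t] > 0.99


class TestSerialization:
    def test_model_json_round_trip_is_bit_exact(self, true_models, tmp_path):
        for t, m in true_models.items():
            f = tmp_path / f"{t}.json"
            m.to_json(f)
            back = ARXModel.from_json(f)
            np.testing.assert_array_equal(back.a, m.a)
            np.testing.assert_array_equal(back.b, m.b)
            assert back.config == m.config
            assert back.target_name == m.target_name
            assert back.sign_convention == m.sign_convention
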