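"""Power-law AGB model fitting, evaluation, jackknife and transfer."""

import numpy as np
import pytest

import lidar_agb as la


class TestFit:
    def test_noiseless_one_variable_exact_recovery(self):
        X = np.array([5.0, 10, 15, 20, 25])
        y = 2.0 * X**1.5
        fit = la.fit_power_model(X, y)
        assert fit.alpha == pytest.approx(2.0, abs=1e-6)
        assert fit.beta == pytest.approx(1.5, abs=1e-6)
        ev = la.evaluate(fit, X, y)
        assert ev.r2 == pytest.approx(1.0, abs=1e-12)
        assert ev.rmse == pytest.approx(0.0, abs=1e-6)

    def test_noiseless_two_variable_exact_recovery(self, rng):
        x1 = rng.uniform(5, 30, 40)
        x2 = rng.uniform(0.3, 1.0, 40)
        y = 3.0 * x1**1.2 * x2**-0.5
        fit = la.fit_power_model(x1, y, "two-variable", x2)
        assert fit.alpha == pytest.approx(3.0, abs=1e-6)
        assert fit.beta == pytest.approx(1.2, abs=1e-6)
        assert fit.gamma == pytest.approx(-0.5, abs=1e-6)

    def test_parameter_recovery_under_lognormal_noise(self):
        # beta_hat unbiased to within 3 Monte-Carlo SEs over 100 replicates
        rng = np.random.default_rng(55)
        betas = []
        for _ in range(100):
            X = rng.uniform(5, 30, 100)
            y = 2.5 * X**1.6 * np.exp(rng.normal(0, 0.2, 100))
            betas.append(la.fit_power_model(X, y).beta)
        betas = np.asarray(betas)
        se = betas.std(ddof=1) / np.sqrt(betas.size)
        assert abs(betas.mean() - 1.6) < 3 * se

    def test_beta_sd_coverage(self):
        # +-2 reported SDs cover the true beta in >= 90% of replicates
        rng = np.random.default_rng(56)
        covered = 0
        for _ in range(100):
            X = rng.uniform(5, 30, 100)
            y = 2.5 * X**1.6 * np.exp(rng.normal(0, 0.2, 100))
            fit = la.fit_power_model(X, y)
            covered += abs(fit.beta - 1.6) <= 2 * fit.beta_sd
        assert covered >= 90

    def test_nls_never_worse_than_log_linear_start(self, rng):
        for trial in range(20):
            X = rng.uniform(5, 30, 30)
            y = 1.5 * X**1.8 * np.exp(rng.normal(0, 0.4, 30))
            design = np.column_stack([np.ones(30), np.log(X)])
            coef, *_ = np.linalg.lstsq(design, np.log(y), rcond=None)
            sse_init = ((y - np.exp(coef[0]) * X**coef[1])**2).sum()
            fit = la.fit_power_model(X, y)
            sse_fit = ((y - fit.predict(X))**2).sum()
            assert sse_fit <= sse_init + 1e-9 * sse_init

    def test_scale_equivariance(self, rng):
        X = rng.uniform(5, 30, 50)
        y = 2.0 * X**1.4 * np.exp(rng.normal(0, 0.2, 50))
        f1 = la.fit_power_model(X, y)
        f2 = la.fit_power_model(X, 100.0 * y)
        assert f2.alpha == pytest.approx(100 * f1.alpha, rel=1e-6)
        assert f2.beta == pytest.approx(f1.beta, abs=1e-7)
        e1 = la.evaluate(f1, X, y)
        e2 = la.evaluate(f2, X, 100.0 * y)
        assert e2.rmse == pytest.approx(100 * e1.rmse, rel=1e-6)
        assert e2.r2 == pytest.approx(e1.r2, abs=1e-9)
        assert e2.rel_rmse == pytest.approx(e1.rel_rmse, rel=1e-9)

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            la.fit_power_model(np.array([1, -2, 3.0]), np.ones(3))
        with pytest.raises(ValueError, match="at least"):
            la.fit_power_model(np.array([1, 2.0]), np.array([1, 2.0]))

    def test_log_scale_mode_is_ols(self, rng):
        X = rng.uniform(5, 30, 30)
        y = 2.0 * X**1.4 * np.exp(rng.normal(0, 0.3, 30))
        fit = la.fit_power_model(X, y, scale="log")
        coef, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(30), np.log(X)]), np.log(y), rcond=None)
        assert fit.alpha == pytest.approx(np.exp(coef[0]), rel=1e-9)
        assert fit.beta == pytest.approx(coef[1], rel=1e-9)


class TestEvaluate:
    def test_perfect_predictions(self):
        fit = la.PowerModelFit("one-variable", 2.0, 1.0)
        X = np.array([1.0, 2, 3])
        ev = la.evaluate(fit, X, 2.0 * X)
        assert ev.r2 == 1.0 and ev.rmse == 0.0 and ev.rel_rmse == 0.0

    def test_hand_checkable_triple(self):
        # y={100,200,300}, yhat={110,190,310}: RMSE=10, relRMSE=5%
        class Fixed:
            form = "one-variable"

            def predict(self, X, x2=None):
                return np.array([110.0, 190.0, 310.0])

        ev = la.evaluate(Fixed(), np.array([1.0, 2, 3]),
                         np.array([100.0, 200, 300]))
        assert ev.rmse == pytest.approx(10.0)
        assert ev.rel_rmse == pytest.approx(5.0)

    def test_constant_prediction_r2_zero(self):
        class Mean:
            form = "one-variable"

            def predict(self, X, x2=None):
                return np.full(X.size, 200.0)

        ev = la.evaluate(Mean(), np.array([1.0, 2, 3]),
                         np.array([100.0, 200, 300]))
        assert ev.r2 == pytest.approx(0.0)


class TestHoldout:
    def test_rounding_at_65(self):
        cal, val = la.holdout_split(np.arange(65), seed=0)
        assert cal.size == 46 and val.size == 19

    def test_seed_determinism(self):
        a = la.holdout_split(np.arange(30), seed=4)
        b = la.holdout_split(np.arange(30), seed=4)
        np.testing.assert_array_equal(a[0], b[0])

    def test_partition_contract(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 200))
            seed = int(rng.integers(0, 2**31))
            cal, val = la.holdout_split(np.arange(n), seed=seed)
            assert set(cal) | set(val) == set(range(n))
            assert not set(cal) & set(val)
            assert cal.size == int(np.round(0.7 * n))

    def test_small_n_directed_to_jackknife(self):
        with pytest.raises(ValueError, match="jackknife"):
            la.holdout_split(np.arange(4))


class TestJackknife:
    def test_noiseless_exact_every_fold(self):
        X = np.linspace(5, 25, 9)
        y = 2.0 * X**1.5
        ev, params = la.jackknife_evaluate(X, y)
        assert params.shape == (9, 2)
        np.testing.assert_allclose(params[:, 0], 2.0, atol=1e-6)
        np.testing.assert_allclose(params[:, 1], 1.5, atol=1e-6)
        assert ev.rmse == pytest.approx(0.0, abs=1e-5)
        assert ev.extra["param_sd"][1] == pytest.approx(0.0, abs=1e-6)

    def test_out_of_fit_pessimism(self):
        # jackknife RMSE >= in-sample RMSE of the full fit, over 20 datasets
        rng = np.random.default_rng(99)
        worse = 0
        for _ in range(20):
            X = rng.uniform(5, 30, 15)
            y = 2.0 * X**1.5 * np.exp(rng.normal(0, 0.3, 15))
            full = la.fit_power_model(X, y)
            in_sample = la.evaluate(full, X, y).rmse
            jack, _ = la.jackknife_evaluate(X, y)
            worse += jack.rmse >= in_sample - 1e-9
        assert worse == 20

    def test_minimum_n(self):
        with pytest.raises(ValueError, match="n >= 4"):
            la.jackknife_evaluate(np.ones(3) * 5, np.ones(3))


class TestCrossDensity:
    def test_identical_metrics_zero_error(self):
        fit = la.PowerModelFit("one-variable", 2.0, 1.5)
        X = np.array([5.0, 10, 15])
        res = la.cross_density_apply(fit, X, X.copy(), 2.0 * X**1.5)
        assert res.error_percent == pytest.approx(0.0)

    def test_mismatched_lengths_rejected(self):
        fit = la.PowerModelFit("one-variable", 2.0, 1.5)
        with pytest.raises(ValueError, match="align"):
            la.cross_density_apply(fit, np.ones(3), np.ones(4), np.ones(3))

    def test_shifted_metrics_give_positive_error(self):
        fit = la.PowerModelFit("one-variable", 2.0, 1.0)
        X = np.array([10.0, 20, 30])
        res = la.cross_density_apply(fit, X, X * 0.9, 2.0 * X)
        # linear predictions: RMS of a 10% shortfall over the reference mean
        pred = 2.0 * X
        expect = 100 * 0.1 * np.sqrt(np.mean(pred**2)) / pred.mean()
        assert res.error_percent == pytest.approx(expect, rel=1e-9)


def test_fit_round_trip_json(tmp_path, rng):
    X = rng.uniform(5, 30, 20)
    y = 2.0 * X**1.5
    fit = la.fit_power_model(X, y, data_model="echo",
                             calibration_density="orig")
    fit.to_json(tmp_path / "fit.json")
    back = la.PowerModelFit.from_json(tmp_path / "fit.json")
    assert back.alpha == pytest.approx(fit.alpha)
    assert back.beta == pytest.approx(fit.beta)
    assert back.data_model == "echo"
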