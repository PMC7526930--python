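"""Member regressors: MLP, RBF network, Takagi-Sugeno ANFIS."""

import json

import numpy as np
import pytest

from chrysopt.regressors import (
    ANFISConfig,
    ANFISModel,
    MLPConfig,
    RBFConfig,
    fit_anfis,
    fit_mlp,
    fit_rbf,
    model_from_dict,
)
from chrysopt.regressors.base import ShapeError, TrainingError
from chrysopt.regressors.rbf import ridge_weights, _design as rbf_design

FITS = {
    "mlp": (fit_mlp, MLPConfig),
    "rbf": (fit_rbf, RBFConfig),
    "anfis": (fit_anfis, ANFISConfig),
}


def _toy(rng, n=40, d=3):
    x = rng.uniform(0, 1, (n, d))
    y = 5 + 3 * x[:, 0] - 2 * x[:, 1] + rng.normal(0, 0.1, n)
    return x, y


@pytest.mark.parametrize("kind", list(FITS))
class TestSharedContracts:
    def test_seeded_fit_is_bit_identical(self, kind, rng):
        fit, cfg_type = FITS[kind]
        x, y = _toy(rng)
        a = fit(x, y, cfg_type(seed=7))
        b = fit(x, y, cfg_type(seed=7))
        probe = rng.uniform(0, 1, (25, x.shape[1]))
        np.testing.assert_array_equal(a.predict(probe), b.predict(probe))

    def test_json_round_trip_preserves_predictions(self, kind, rng):
        fit, cfg_type = FITS[kind]
        x, y = _toy(rng)
        model = fit(x, y, cfg_type(seed=1))
        clone = model_from_dict(json.loads(json.dumps(model.to_dict())))
        probe = rng.uniform(0, 1, (25, x.shape[1]))
        np.testing.assert_array_equal(model.predict(probe), clone.predict(probe))

    def test_feature_count_mismatch_raises(self, kind, rng):
        fit, cfg_type = FITS[kind]
        x, y = _toy(rng)
        model = fit(x, y, cfg_type(seed=1))
        with pytest.raises(ShapeError):
            model.predict(np.zeros((4, x.shape[1] + 2)))

    def test_constant_targets_give_constant_predictions(self, kind, rng):
        fit, cfg_type = FITS[kind]
        x = rng.uniform(0, 1, (30, 4))
        model = fit(x, np.full(30, 7.0), cfg_type(seed=0))
        probe = rng.uniform(0, 1, (20, 4))
        np.testing.assert_allclose(model.predict(probe), 7.0, atol=1e-2)

    def test_linear_surface_recovered(self, kind, rng):
        # all members express an affine map; noiseless fit should be near-exact
        fit, cfg_type = FITS[kind]
        x = rng.uniform(0, 1, (400, 11))
        beta = rng.uniform(-2, 2, 11)
        y = 10 + x @ beta
        model = fit(x[:300], y[:300], cfg_type(seed=1))
        pred = model.predict(x[300:])
        resid = y[300:] - pred
        r2 = 1 - (resid**2).sum() / ((y[300:] - y[300:].mean()) ** 2).sum()
        assert r2 > 0.99


class TestMLP:
    def test_learns_linear_map_within_tolerance(self, rng):
        x = rng.uniform(0, 1, (50, 1))
        y = 2 * x.ravel()
        model = fit_mlp(x, y)
        rmse = np.sqrt(np.mean((model.predict(x) - y) ** 2))
        assert rmse < 0.05 * np.ptp(y)

    def test_divergence_raises_training_error(self, rng):
        x, y = _toy(rng)
        with pytest.raises(TrainingError, match="learning rate"):
            fit_mlp(x, 100 * y, MLPConfig(learning_rate=50.0, momentum=0.0, seed=0))

    def test_epoch_losses_decrease_overall(self, rng):
        x, y = _toy(rng, n=60)
        model = fit_mlp(x, y, MLPConfig(seed=2))
        losses = np.array(model.loss_history)
        assert losses[-1] < losses[0]
        # mini-batch noise allowed, but no sustained blow-up
        assert losses.min() * 5 > losses[-1] - 1e-9


class TestRBF:
    def test_exact_interpolation_limit(self, rng):
        x = rng.uniform(0, 1, (5, 2))
        y = rng.uniform(0, 10, 5)
        model = fit_rbf(x, y, RBFConfig(n_centers=5, ridge=1e-10))
        assert np.abs(model.predict(x) - y).max() < 1e-6

    def test_sine_fit(self, rng):
        x = rng.uniform(0, 1, (100, 1))
        y = np.sin(2 * np.pi * x.ravel())
        model = fit_rbf(x, y, RBFConfig(seed=1))
        test_x = rng.uniform(0, 1, (200, 1))
        rmse = np.sqrt(np.mean((model.predict(test_x) - np.sin(2 * np.pi * test_x.ravel())) ** 2))
        assert rmse < 0.1

    def test_weights_match_normal_equations_oracle(self, rng):
        # with centers/widths fixed, the output layer must equal the
        # explicit ridge normal-equations solution
        x, y = _toy(rng, n=50)
        cfg = RBFConfig(n_centers=6, seed=3)
        model = fit_rbf(x, y, cfg)
        phi = rbf_design(x, model.centers, model.sigmas, cfg.linear_tail)
        k = phi.shape[1]
        penalty = np.eye(k) * cfg.ridge
        penalty[-1, -1] = 0.0
        oracle = np.linalg.solve(phi.T @ phi + penalty, phi.T @ y)
        np.testing.assert_allclose(model.weights, oracle, atol=1e-8)

    def test_more_centers_than_points_rejected(self, rng):
        x = rng.uniform(0, 1, (5, 2))
        with pytest.raises(ValueError, match="distinct"):
            fit_rbf(x, np.ones(5), RBFConfig(n_centers=10))


class TestANFIS:
    def test_firing_strengths_normalize_to_one(self, rng):
        x, y = _toy(rng, n=80, d=4)
        model = fit_anfis(x, y, ANFISConfig(seed=4))
        wn = model.firing_strengths(rng.uniform(-1, 2, (200, 4)))
        np.testing.assert_allclose(wn.sum(axis=1), 1.0, atol=1e-12)
        assert (wn >= 0).all()

    def test_single_rule_constant_consequent(self):
        model = ANFISModel(
            model_kind="anfis",
            n_features=2,
            config=ANFISConfig(n_rules=1),
            centers=np.array([[0.5, 0.5]]),
            sigmas=np.array([[0.3, 0.3]]),
            consequents=np.array([[0.0, 0.0, 3.0]]),
        )
        probe = np.random.default_rng(0).uniform(0, 1, (50, 2))
        np.testing.assert_allclose(model.predict(probe), 3.0, atol=1e-12)

    def test_two_rule_weighted_sum_defuzzification(self):
        # memberships normalizing to 0.2/0.8 with consequents 10 and 20 -> 18
        model = ANFISModel(
            model_kind="anfis",
            n_features=1,
            config=ANFISConfig(n_rules=2),
            centers=np.array([[0.0], [1.0]]),
            sigmas=np.array([[1.0], [1.0]]),
            consequents=np.array([[0.0, 10.0], [0.0, 20.0]]),
        )
        # solve for the input whose normalized firings are (0.2, 0.8):
        # w2/w1 = exp((x - 0)^2/2 - (x-1)^2/2) = exp(x - 1/2) = 4
        x_star = 0.5 + np.log(4.0)
        pred = model.predict(np.array([[x_star]]))
        np.testing.assert_allclose(pred, 18.0, atol=1e-12)

    def test_additive_surface_fit(self, rng):
        x = rng.uniform(0, 1, (200, 2))
        y = x[:, 0] + x[:, 1]
        model = fit_anfis(x, y, ANFISConfig(seed=5))
        probe = rng.uniform(0, 1, (100, 2))
        rmse = np.sqrt(np.mean((model.predict(probe) - probe.sum(axis=1)) ** 2))
        assert rmse < 0.05 * 2.0

    def test_hybrid_training_loss_non_increasing(self, rng):
        x, y = _toy(rng, n=60, d=3)
        model = fit_anfis(x, y, ANFISConfig(seed=6))
        losses = model.loss_history
        assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))
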