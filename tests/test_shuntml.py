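"""MLP shunt inverter: architecture arithmetic, training, prediction."""

import numpy as np
import pytest

from vqshunt import evalstats, scenarios as sc, shuntml
from vqshunt.config import MLPConfig


def enumerate_params(cfg: MLPConfig) -> int:
    """Independent oracle: list every weight matrix and bias vector."""
    sizes = [cfg.n_features] + [cfg.units_per_layer] * cfg.hidden_layers \
        + [cfg.output_units]
    total = 0
    for a, b in zip(sizes[:-1], sizes[1:]):
        total += a * b + b
    return total


class TestCountParams:
    def test_default_architecture(self):
        assert shuntml.count_params(MLPConfig()) == 84097

    def test_no_hidden_layers(self):
        assert shuntml.count_params(MLPConfig(hidden_layers=0)) == 11

    def test_small_architecture_by_hand(self):
        # f=3, L=2, u=4, o=1: 3*4+4 + 4*4+4 + 4+1 = 41
        cfg = MLPConfig(n_features=3, hidden_layers=2, units_per_layer=4)
        assert shuntml.count_params(cfg) == 41

    def test_matches_enumeration_on_random_configs(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            cfg = MLPConfig(n_features=int(rng.integers(1, 20)),
                            hidden_layers=int(rng.integers(0, 7)),
                            units_per_layer=int(rng.integers(1, 200)),
                            output_units=int(rng.integers(1, 4)))
            assert shuntml.count_params(cfg) == enumerate_params(cfg)

    def test_matches_fitted_backend_weights(self, small_ds):
        # the formula agrees with the actual weight arrays of a fitted model
        cfg = MLPConfig(hidden_layers=2, units_per_layer=8, epochs=3)
        model = shuntml.train(small_ds, cfg)
        est = model.estimator
        n = sum(w.size for w in est.coefs_) + sum(b.size for b in est.intercepts_)
        assert n == shuntml.count_params(cfg)


class TestTraining:
    def test_constant_label_regression(self, small_ds, small_mlp_cfg):
        ds = sc.ScenarioDataset(records=small_ds.records.copy(),
                                seed=small_ds.seed)
        ds.records["shunt"] = 20.0
        model = shuntml.train(ds, small_mlp_cfg)
        pred = shuntml.predict(model, ds.test)
        # a finite run of a stochastic optimizer: near, not exactly, constant
        assert abs(pred.mean() - 20.0) < 0.1
        assert pred.std() < 0.5
        assert np.abs(pred - 20.0).max() < 2.0

    def test_permuted_labels_destroy_signal(self, small_ds, small_mlp_cfg):
        ds = sc.ScenarioDataset(records=small_ds.records.copy(),
                                seed=small_ds.seed)
        rng = np.random.default_rng(1)
        tr = ds.records["split"] == "train"
        ds.records.loc[tr, "shunt"] = rng.permutation(
            ds.records.loc[tr, "shunt"].to_numpy())
        model = shuntml.train(ds, small_mlp_cfg)
        pred = shuntml.predict(model, ds.test)
        reg = evalstats.regress_actual_on_estimate(
            ds.test["shunt"].to_numpy(), pred)
        assert reg.r_squared < 0.2

    def test_real_labels_recoverable(self, small_ds, small_mlp_cfg):
        # even a light architecture learns most of the forward map
        model = shuntml.train(small_ds, small_mlp_cfg)
        pred = shuntml.predict(model, small_ds.test)
        reg = evalstats.regress_actual_on_estimate(
            small_ds.test["shunt"].to_numpy(), pred)
        assert reg.r_squared > 0.8

    def test_normalization_from_training_rows_only(self, small_ds, small_mlp_cfg):
        model = shuntml.train(small_ds, small_mlp_cfg)
        x = small_ds.train[shuntml.FEATURE_COLUMNS].to_numpy()
        # statistics derive from (a subset of) training rows: they must be
        # far closer to the train stats than to deliberately shifted ones
        assert np.allclose(model.feat_mean, x.mean(axis=0),
                           atol=0.2 * np.abs(x.mean(axis=0)) + 0.2)
        assert (model.feat_std > 0).all()

    def test_train_prediction_consistency(self, small_ds, small_mlp_cfg):
        # backend loss is 0.5*MSE on the fitted rows; the full-train MSE
        # must be commensurate with the final training loss
        model = shuntml.train(small_ds, small_mlp_cfg)
        pred = shuntml.predict(model, small_ds.train)
        mse = float(np.mean((pred - small_ds.train["shunt"].to_numpy()) ** 2))
        assert 0.5 * mse <= 2.0 * model.loss_history[-1] + 0.05

    def test_loss_history_decreases(self, small_ds, small_mlp_cfg):
        model = shuntml.train(small_ds, small_mlp_cfg)
        h = np.array(model.loss_history)
        # smoothed tail well below smoothed head
        assert h[-10:].mean() < 0.2 * h[:10].mean()

    def test_missing_feature_is_named(self, small_ds, small_mlp_cfg):
        model = shuntml.train(small_ds, small_mlp_cfg)
        broken = small_ds.test.drop(columns=["mean_paco2"])
        with pytest.raises(KeyError, match="mean_paco2"):
            shuntml.predict(model, broken)

    def test_estimates_in_physiologic_range(self, small_ds, small_mlp_cfg):
        model = shuntml.train(small_ds, small_mlp_cfg)
        pred = shuntml.predict(model, small_ds.test)
        assert (pred > -5).all() and (pred < 50).all()

    def test_empty_training_split_rejected(self, small_ds, small_mlp_cfg):
        ds = sc.ScenarioDataset(records=small_ds.records[
            small_ds.records["split"] == "test"].copy(), seed=0)
        with pytest.raises(ValueError):
            shuntml.train(ds, small_mlp_cfg)


class TestPersistence:
    def test_save_load_round_trip(self, small_ds, small_mlp_cfg, tmp_path):
        model = shuntml.train(small_ds, small_mlp_cfg)
        p = tmp_path / "m.joblib"
        shuntml.save_model(model, p)
        back = shuntml.load_model(p)
        np.testing.assert_array_equal(
            shuntml.predict(back, small_ds.test),
            shuntml.predict(model, small_ds.test))
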