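import math

import numpy as np
import pytest

from rowkinetics import nn
from rowkinetics.model import (
    ModelError,
    NetworkConfig,
    RowingKineticsModel,
    TrainConfig,
    build_network,
    leave_one_out,
    lstm_param_count,
    sample_search_space,
    split_indices,
)


class TestArchitecture:
    def test_lstm_parameter_count_closed_form(self):
        net = build_network(NetworkConfig(n_inputs=16, lstm_units=500))
        assert net.n_lstm_params() == lstm_param_count(16, 500) == 1_034_000

    def test_closed_form_against_hand_count_tiny(self):
        """Hand count at units=2, inputs=3: four gates, each with a 3x2 input
        block, a 2x2 recurrent block and 2 biases -> 4*(6+4+2) = 48."""
        hand = 4 * (3 * 2 + 2 * 2 + 2)
        assert lstm_param_count(3, 2) == hand
        net = nn.LSTMRegressor(n_in=3, units=2, n_out=6)
        assert net.n_lstm_params() == hand

    def test_boat_architecture_builds(self):
        net = build_network(NetworkConfig(n_inputs=18, lstm_units=53, dropout=0.10))
        assert net.units == 53
        assert net.dropout == 0.10

    def test_unusual_input_width_warns(self):
        with pytest.warns(UserWarning):
            build_network(NetworkConfig(n_inputs=7, lstm_units=16))

    def test_prediction_shape_contract(self, rng):
        net = build_network(NetworkConfig(n_inputs=16, lstm_units=12))
        for T in (5, 37, 160):
            X = rng.normal(size=(2, T, 16)).astype(np.float32)
            assert net.forward(X).shape == (2, T, 6)

    def test_dropout_inactive_at_eval(self, rng):
        net = build_network(NetworkConfig(n_inputs=16, lstm_units=12, dropout=0.10))
        X = rng.normal(size=(1, 20, 16)).astype(np.float32)
        np.testing.assert_array_equal(net.forward(X), net.forward(X))

    def test_zero_dropout_train_equals_eval(self, rng):
        net = build_network(NetworkConfig(n_inputs=16, lstm_units=12, dropout=0.0))
        X = rng.normal(size=(1, 20, 16)).astype(np.float32)
        np.testing.assert_array_equal(
            net.forward(X, train=True, rng=np.random.default_rng(0)), net.forward(X)
        )


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """BPTT gradients agree with central finite differences on a tiny net."""
        net = nn.LSTMRegressor(n_in=3, units=4, n_out=2, seed=7, dtype=np.float64)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(2, 6, 3))
        Y = rng.normal(size=(2, 6, 2))
        mask = np.ones((2, 6))
        mask[1, 4:] = 0.0  # include padding in the check

        def loss_fn():
            pred = net.forward(X)
            return nn.masked_mse_and_grad(pred, Y, mask)[0]

        pred, cache = net.forward(X, want_cache=True)
        _, dY = nn.masked_mse_and_grad(pred, Y, mask)
        grads = net.backward(cache, dY)
        eps = 1e-6
        for name, param in net.params.items():
            flat = param.ravel()
            idxs = rng.choice(flat.size, size=min(8, flat.size), replace=False)
            for i in idxs:
                orig = flat[i]
                flat[i] = orig + eps
                up = loss_fn()
                flat[i] = orig - eps
                down = loss_fn()
                flat[i] = orig
                fd = (up - down) / (2 * eps)
                assert grads[name].ravel()[i] == pytest.approx(fd, rel=1e-4, abs=1e-8), name

    def test_padding_does_not_affect_real_frames(self, rng):
        net = nn.LSTMRegressor(n_in=4, units=5, n_out=6, seed=0)
        x = rng.normal(size=(1, 10, 4)).astype(np.float32)
        x_padded = np.concatenate([x, np.zeros((1, 7, 4), np.float32)], axis=1)
        np.testing.assert_allclose(
            net.forward(x)[0], net.forward(x_padded)[0, :10], atol=1e-6
        )


class TestSearchSpace:
    def test_bounds_respected(self):
        samples = sample_search_space(10_000, seed=3)
        units = np.array([u for u, _ in samples])
        assert units.min() >= 10 and units.max() <= 500
        assert set(d for _, d in samples) <= {0.0, 0.05, 0.10}

    def test_log_uniform_median(self):
        """Median of exp(U(ln 10, ln 500)) is sqrt(10*500) ~ 70.7."""
        samples = sample_search_space(10_000, seed=4)
        med = np.median([u for u, _ in samples])
        assert 60 <= med <= 82

    def test_single_trial_allowed_zero_rejected(self):
        assert len(sample_search_space(1, seed=0)) == 1
        with pytest.raises(ModelError):
            sample_search_space(0, seed=0)


class TestSplits:
    def test_split_is_stratified_and_disjoint(self, small_dataset):
        train_idx, val_idx = split_indices(small_dataset, TrainConfig(seed=5))
        assert set(train_idx).isdisjoint(val_idx)
        assert len(train_idx) + len(val_idx) == len(small_dataset)
        groups = small_dataset.by_subject()
        for subject, idxs in groups.items():
            n_val = len(set(idxs) & set(val_idx))
            assert n_val == max(1, round(0.2 * len(idxs)))


class TestTraining:
    def _configs(self, n_units=12, epochs=8):
        return (
            NetworkConfig(n_inputs=16, lstm_units=n_units, seed=0),
            TrainConfig(max_epochs=epochs, patience_epochs=epochs - 1, seed=0),
        )

    def test_training_reduces_validation_rmse(self, small_dataset):
        net_cfg, train_cfg = self._configs(n_units=16, epochs=10)
        res = RowingKineticsModel(small_dataset, net_cfg, train_cfg).fit()
        h = res.history
        assert h["val_rmse"].iloc[-1] < h["val_rmse"].iloc[0]
        assert len(h) >= 1 and res.trained.best_epoch >= 0

    def test_identical_seeds_identical_histories(self, small_dataset):
        net_cfg, train_cfg = self._configs()
        a = RowingKineticsModel(small_dataset, net_cfg, train_cfg).fit()
        b = RowingKineticsModel(small_dataset, net_cfg, train_cfg).fit()
        assert a.history.equals(b.history)
        for k in a.trained.weights:
            np.testing.assert_array_equal(a.trained.weights[k], b.trained.weights[k])

    def test_early_stopping_on_unlearnable_validation(self, small_dataset, rng):
        """Noise targets in validation stall improvement and trigger the stop."""
        ds = small_dataset
        net_cfg = NetworkConfig(n_inputs=16, lstm_units=12, seed=0)
        train_cfg = TrainConfig(max_epochs=500, patience_epochs=5, seed=0)
        model = RowingKineticsModel(ds, net_cfg, train_cfg)
        train_idx, val_idx = split_indices(ds, train_cfg)
        # corrupt validation targets with white noise (temporarily)
        saved = [ds.records[i].Y for i in val_idx]
        try:
            for i in val_idx:
                ds.records[i].Y = rng.normal(
                    0, 1e4, ds.records[i].Y.shape
                )
            res = model.fit(train_idx, val_idx)
            assert len(res.history) < 100  # stopped long before max_epochs
        finally:
            for i, y in zip(val_idx, saved):
                ds.records[i].Y = y

    def test_empty_validation_rejected(self, small_dataset):
        net_cfg, train_cfg = self._configs()
        model = RowingKineticsModel(small_dataset, net_cfg, train_cfg)
        with pytest.raises(ModelError):
            model.fit(np.arange(len(small_dataset)), np.array([], dtype=int))

    def test_predictions_denormalized_to_physical_scale(self, small_dataset):
        net_cfg, train_cfg = self._configs(n_units=16, epochs=10)
        res = RowingKineticsModel(small_dataset, net_cfg, train_cfg).fit()
        recs = [small_dataset.records[i] for i in res.val_idx]
        preds = res.predict(recs)
        assert all(p.shape == (len(r), 6) for p, r in zip(preds, recs))
        # after a few epochs predictions live on the physical scale (hundreds
        # of newtons / watts), not the z-scored scale
        peak = max(np.abs(p).max() for p in preds)
        assert peak > 50.0

    def test_summary_mentions_architecture(self, small_dataset):
        net_cfg, train_cfg = self._configs()
        res = RowingKineticsModel(small_dataset, net_cfg, train_cfg).fit()
        text = res.summary()
        assert "LSTM(12)" in text
        assert "MAE_norm" in text


class TestRandomSearch:
    def test_best_trial_minimizes_drive_mae(self, small_dataset):
        from rowkinetics.model import random_search

        tc = TrainConfig(max_epochs=2, patience_epochs=1, seed=0)
        best, trials = random_search(small_dataset, n_trials=2, seed=11, train_config=tc)
        assert len(trials) == 2
        assert best.lstm_units == int(trials.loc[trials.drive_mae.idxmin(), "units"])
        assert (trials.drive_mae > 0).all()


class TestLeaveOneOut:
    def test_fold_structure(self, small_dataset):
        net_cfg = NetworkConfig(n_inputs=16, lstm_units=12, seed=0)
        cfg = TrainConfig(max_epochs=3, patience_epochs=2, seed=0)
        res = leave_one_out(small_dataset, net_cfg, cfg)
        subjects = small_dataset.subjects
        assert set(res.folds) == set(subjects)
        groups = small_dataset.by_subject()
        all_val = []
        for subject, fold in res.folds.items():
            assert sorted(fold.val_idx.tolist()) == sorted(groups[subject])
            val_subjects = {small_dataset.records[i].subject_id for i in fold.val_idx}
            train_subjects = {small_dataset.records[i].subject_id for i in fold.train_idx}
            assert val_subjects == {subject}
            assert subject not in train_subjects
            all_val.extend(fold.val_idx.tolist())
        assert sorted(all_val) == list(range(len(small_dataset)))

    def test_aggregate_is_mean_of_folds(self, small_dataset):
        net_cfg = NetworkConfig(n_inputs=16, lstm_units=12, seed=0)
        cfg = TrainConfig(max_epochs=3, patience_epochs=2, seed=0)
        res = leave_one_out(small_dataset, net_cfg, cfg)
        maes = [r.mean_mae_norm_pct for r in
                (res.folds[s].evaluate(subject_level=False) for s in res.folds)]
        assert res.mean_mae_norm_pct == pytest.approx(np.mean(maes))

    def test_needs_three_subjects(self, small_dataset):
        two = type(small_dataset)(
            records=[r for r in small_dataset.records
                     if r.subject_id in small_dataset.subjects[:2]],
            feature_names=small_dataset.feature_names,
            condition=small_dataset.condition,
        )
        with pytest.raises(ModelError):
            leave_one_out(two, NetworkConfig(n_inputs=16, lstm_units=12),
                          TrainConfig(max_epochs=3, patience_epochs=2))
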