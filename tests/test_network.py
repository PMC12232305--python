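"""Network construction, gradients, training protocol and inference."""

import numpy as np
import pytest

from flimforge.network import (
    LifetimeRegressionModel,
    NetworkConfig,
    TrainingConfig,
    build_network,
    load_checkpoint,
    make_training_pairs,
    normalize_stack,
    predict_map,
    train_model,
)
from flimforge.network.layers import AdamW
from flimforge.simulate import two_region_fixture


def tiny_config(seed=0, **kw):
    kw.setdefault("in_time_bins", 8)
    kw.setdefault("stage_channels", (8, 16))
    kw.setdefault("width_multiplier", 0.5)
    return NetworkConfig(seed=seed, **kw)


class TestBuild:
    def test_output_shape_preserves_spatial_resolution(self):
        net = build_network(tiny_config())
        x = np.random.default_rng(0).random((2, 8, 12, 12))
        assert net.forward(x, train=False).shape == (2, 12, 12)

    def test_outputs_nonnegative(self):
        net = build_network(tiny_config())
        x = np.random.default_rng(1).random((1, 8, 8, 8))
        assert net.forward(x, train=False).min() >= 0

    def test_wider_network_has_more_parameters(self):
        small = build_network(tiny_config(width_multiplier=0.5))
        large = build_network(tiny_config(width_multiplier=1.0))
        assert large.n_parameters() > small.n_parameters()

    def test_indivisible_spatial_dims_instruct_padding(self):
        net = build_network(tiny_config())
        with pytest.raises(ValueError, match="pad"):
            net.forward(np.zeros((1, 8, 9, 9)))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """End-to-end gradient check of the assembled network."""
        rng = np.random.default_rng(3)
        net = build_network(tiny_config(seed=3))
        x = rng.random((2, 8, 8, 8))
        y = rng.random((2, 8, 8))

        def loss():
            pred = net.forward(x, train=True)
            return float(np.mean((pred - y) ** 2))

        pred = net.forward(x, train=True)
        grad = 2.0 * (pred - y) / pred.size
        for p in net.parameters():
            p.grad[...] = 0.0
        net.backward(grad)

        eps = 1e-6
        checked = 0
        for p in net.parameters()[::7]:
            flat = p.data.ravel()
            idx = rng.integers(flat.size)
            orig = flat[idx]
            flat[idx] = orig + eps
            lp = loss()
            flat[idx] = orig - eps
            lm = loss()
            flat[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            analytic = p.grad.ravel()[idx]
            assert analytic == pytest.approx(numeric, rel=5e-3, abs=1e-8)
            checked += 1
        assert checked >= 3


class TestTrainingPairs:
    def _data(self, n=10):
        data = two_region_fixture(n, seed=0, size=8)
        return [d[0] for d in data], [d[1] for d in data]

    def test_80_20_split(self):
        stacks, maps = self._data(10)
        train, val = make_training_pairs(stacks, maps, TrainingConfig(seed=0))
        assert len(train[0]) == 8 and len(val[0]) == 2

    def test_channel_max_is_one(self):
        stacks, maps = self._data(4)
        (X, _, _), _ = make_training_pairs(stacks, maps, TrainingConfig(seed=0))
        peaks = X.max(axis=1)
        assert np.allclose(peaks, 1.0)

    def test_split_determinism(self):
        stacks, maps = self._data(10)
        a, _ = make_training_pairs(stacks, maps, TrainingConfig(seed=5))
        b, _ = make_training_pairs(stacks, maps, TrainingConfig(seed=5))
        assert np.array_equal(a[0], b[0])

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            make_training_pairs([], [], TrainingConfig())


class TestTrainingLoop:
    def _small_setup(self, n=8, seed=0):
        data = two_region_fixture(n, seed=seed, size=8)
        stacks, maps = [d[0] for d in data], [d[1] for d in data]
        cfg = NetworkConfig(in_time_bins=stacks[0].axis.n_bins,
                            stage_channels=(8, 16), width_multiplier=0.5, seed=seed)
        return stacks, maps, cfg

    def test_stops_exactly_patience_epochs_after_last_improvement(self):
        """When early stopping triggers, the run must end exactly
        ``patience`` epochs after the best validation epoch."""
        stacks, maps, cfg = self._small_setup()
        net = build_network(cfg)
        data = make_training_pairs(stacks, maps, TrainingConfig(seed=0))
        tc = TrainingConfig(patience=3, max_epochs=300, seed=0)
        _, history = train_model(net, data, tc)
        assert len(history) < tc.max_epochs, "early stopping never triggered"
        val = [h["val_mse"] for h in history]
        best = int(np.argmin(val))
        assert len(history) - 1 - best == tc.patience

    def test_overfit_probe_reduces_training_loss(self):
        stacks, maps, cfg = self._small_setup()
        net = build_network(cfg)
        data = make_training_pairs(stacks, maps, TrainingConfig(seed=0))
        _, history = train_model(net, data, TrainingConfig(max_epochs=10, seed=0))
        assert history[-1]["train_loss"] < history[0]["train_loss"]

    def test_history_bounded_by_max_epochs(self):
        stacks, maps, cfg = self._small_setup()
        net = build_network(cfg)
        data = make_training_pairs(stacks, maps, TrainingConfig(seed=0))
        _, history = train_model(net, data, TrainingConfig(max_epochs=3, seed=0))
        assert len(history) <= 3


class TestInference:
    def _fitted(self):
        data = two_region_fixture(8, seed=2, size=8)
        stacks, maps = [d[0] for d in data], [d[1] for d in data]
        model = LifetimeRegressionModel(
            stacks, maps,
            network_config=NetworkConfig(in_time_bins=stacks[0].axis.n_bins,
                                         stage_channels=(8, 16),
                                         width_multiplier=0.5, seed=0),
            training_config=TrainingConfig(max_epochs=3, seed=0),
        )
        return model.fit(), stacks

    def test_predict_shape_and_determinism(self):
        res, stacks = self._fitted()
        a = res.predict(stacks[0])
        b = res.predict(stacks[0])
        assert a.tau.shape == stacks[0].spatial_shape
        assert np.array_equal(a.tau, b.tau)
        assert a.tau.min() >= 0

    def test_bin_mismatch_instructs_resampling(self):
        res, stacks = self._fitted()
        from flimforge.axes import TimeAxis
        from flimforge.simulate import FLIMStack

        other = FLIMStack(counts=np.zeros((32, 8, 8), dtype=int),
                          axis=TimeAxis(0.1, 32))
        with pytest.raises(ValueError, match="resample_time_axis"):
            res.predict(other)

    def test_summary_reports_fit(self):
        res, _ = self._fitted()
        text = res.summary()
        assert "AdamW" in text and "validation MSE" in text

    def test_checkpoint_round_trip(self, tmp_path):
        res, stacks = self._fitted()
        path = tmp_path / "model.npz"
        res.save(path)
        net, meta = load_checkpoint(path)
        reload_pred = predict_map(net, stacks[0])
        assert np.allclose(reload_pred.tau, res.predict(stacks[0]).tau)
        assert meta["bin_width"] == stacks[0].axis.bin_width


class TestAdamW:
    def test_decoupled_weight_decay_shrinks_parameters(self):
        from flimforge.network.layers import Parameter

        p = Parameter(np.array([10.0]))
        opt = AdamW([p], lr=0.1, weight_decay=0.5)
        p.grad[...] = 0.0
        opt.step()
        assert p.data[0] < 10.0  # decay acts even with zero gradient
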