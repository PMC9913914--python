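"""Architecture structure, gradient correctness, training behaviour."""

import numpy as np
import pytest

from glucoforecast import (
    ModelSpec,
    StandardizerState,
    TrainingSpec,
    WindowSpec,
    build_forecaster,
    load_checkpoint,
    make_windows,
    predict_horizon,
    save_checkpoint,
    train_forecaster,
)
from glucoforecast.nn import LSTM, Bidirectional, Dense, LeakyReLU, Network

IDENTITY = StandardizerState(mean=np.zeros(1), sd=np.ones(1))


def small_spec(**kw):
    defaults = dict(layer1_units=8, layer2_units=4, dropout_rate=0.0)
    defaults.update(kw)
    return ModelSpec(**defaults)


class TestBuild:
    def test_default_shapes_30min(self):
        net = build_forecaster(small_spec(), n_channels=1)
        out = net.forward(np.zeros((5, 6, 1)))
        assert out.shape == (5, 6)

    def test_60min_two_channels(self):
        net = build_forecaster(small_spec(horizon_len=12), n_channels=2)
        out = net.forward(np.zeros((3, 12, 2)))
        assert out.shape == (3, 12)

    def test_vanilla_has_one_recurrent_layer(self):
        net = build_forecaster(small_spec(stacked=False), n_channels=1)
        assert sum(isinstance(l, (LSTM, Bidirectional)) for l in net.layers) == 1

    def test_stacked_has_two_recurrent_layers(self):
        net = build_forecaster(small_spec(), n_channels=1)
        assert sum(isinstance(l, LSTM) for l in net.layers) == 2

    def test_bidirectional_doubles_recurrent_width(self):
        uni = build_forecaster(small_spec(), 1)
        bi = build_forecaster(small_spec(bidirectional=True), 1)
        assert bi.n_params > uni.n_params

    @pytest.mark.parametrize("change, grows", [
        (dict(layer1_units=16), True),
        (dict(horizon_len=12), True),
        (dict(dropout_rate=0.3), False),
        (dict(leaky_relu_slope=0.1), False),
    ])
    def test_param_count_tracks_structure_only(self, change, grows):
        base = build_forecaster(small_spec(), 1).n_params
        other = build_forecaster(small_spec(**change), 1).n_params
        assert (other > base) if grows else (other == base)

    def test_channel_count_changes_params(self):
        assert (build_forecaster(small_spec(), 3).n_params
                > build_forecaster(small_spec(), 1).n_params)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """BPTT gradients agree with central finite differences."""
        rng = np.random.default_rng(0)
        net = Network([LSTM(2, 5, True), LeakyReLU(0.01),
                       LSTM(5, 4, False), Dense(4, 3)])
        net.init_weights(np.random.default_rng(1))
        x = rng.normal(size=(3, 4, 2))
        y = rng.normal(size=(3, 3))
        net.loss_and_grad(x, y, train=False)
        eps = 1e-6
        for name, p, g, key in net.iter_params():
            W = p[key]
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in W.shape)
                orig = W[idx]
                W[idx] = orig + eps
                lp = float(np.mean((net.forward(x) - y) ** 2))
                W[idx] = orig - eps
                lm = float(np.mean((net.forward(x) - y) ** 2))
                W[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert numeric == pytest.approx(g[key][idx], rel=1e-3, abs=1e-7), name

    def test_bidirectional_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        net = Network([Bidirectional(1, 3, True), Bidirectional(6, 2, False),
                       Dense(4, 2)])
        net.init_weights(np.random.default_rng(3))
        x = rng.normal(size=(2, 5, 1))
        y = rng.normal(size=(2, 2))
        net.loss_and_grad(x, y, train=False)
        eps = 1e-6
        for name, p, g, key in net.iter_params():
            W = p[key]
            idx = tuple(rng.integers(0, s) for s in W.shape)
            orig = W[idx]
            W[idx] = orig + eps
            lp = float(np.mean((net.forward(x) - y) ** 2))
            W[idx] = orig - eps
            lm = float(np.mean((net.forward(x) - y) ** 2))
            W[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert numeric == pytest.approx(g[key][idx], rel=1e-3, abs=1e-7), name


class TestTraining:
    def test_constant_target_converges_to_zero_loss(self):
        x = np.zeros((64, 6, 1))
        y = np.full((64, 6), 0.5)
        net = build_forecaster(small_spec(), 1)
        model = train_forecaster(net, x, y,
                                 TrainingSpec(max_epochs=200, seed=0,
                                              learning_rate=0.01,
                                              early_stop_patience=200),
                                 IDENTITY, model_spec=small_spec())
        losses = model.history["train_loss"]
        assert losses[-1] < 1e-3
        # loss is non-increasing (up to tiny numerical wiggle) on this
        # degenerate noiseless problem
        assert losses[-1] <= losses[0]

    def test_sinusoid_beats_series_sd(self):
        t = np.arange(1200)
        sig = np.sin(2 * np.pi * t / 48)
        x, y, _ = make_windows(sig, sig, WindowSpec(6, 6, stride=1),
                               tail="strict")
        net = build_forecaster(small_spec(layer1_units=16, layer2_units=8), 1)
        model = train_forecaster(
            net, x, y,
            TrainingSpec(max_epochs=60, seed=0, learning_rate=3e-3),
            IDENTITY, model_spec=small_spec(),
        )
        pred = model.network.forward(x, train=False)
        rmse = np.sqrt(np.mean((pred - y) ** 2))
        assert rmse < sig.std()

    def test_same_seed_same_first_epoch_loss(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(50, 6, 1))
        y = rng.normal(size=(50, 6))
        losses = []
        for _ in range(2):
            net = build_forecaster(small_spec(dropout_rate=0.2), 1)
            model = train_forecaster(net, x, y,
                                     TrainingSpec(max_epochs=1, seed=42),
                                     IDENTITY, model_spec=small_spec())
            losses.append(model.history["train_loss"][0])
        assert losses[0] == losses[1]

    def test_shape_mismatch_rejected(self):
        net = build_forecaster(small_spec(), 1)
        with pytest.raises(ValueError, match="shape"):
            train_forecaster(net, np.zeros((10, 6, 1)), np.zeros((9, 6)),
                             TrainingSpec(), IDENTITY)


@pytest.fixture(scope="module")
def trained():
    rng = np.random.default_rng(0)
    x = rng.normal(100, 10, size=(40, 6, 1))
    y = rng.normal(100, 10, size=(40, 6))
    state = StandardizerState(mean=np.array([100.0]), sd=np.array([10.0]))
    from glucoforecast import apply_standardizer
    net = build_forecaster(small_spec(), 1)
    return train_forecaster(net, apply_standardizer(state, x),
                            (y - 100.0) / 10.0,
                            TrainingSpec(max_epochs=3, seed=0), state,
                            model_spec=small_spec())


class TestPredict:

    def test_output_length_is_horizon(self, trained):
        out = predict_horizon(trained, np.full((6, 1), 110.0))
        assert out.shape == (6,)

    def test_output_finite_and_in_mgdl_scale(self, trained):
        out = predict_horizon(trained, np.full((6, 1), 110.0))
        assert np.all(np.isfinite(out))
        assert np.all((out > 0) & (out < 600))  # plausible mg/dL, not z-scores

    def test_shape_mismatch_rejected(self, trained):
        with pytest.raises(ValueError, match="channel"):
            predict_horizon(trained, np.zeros((6, 2)))

    def test_checkpoint_round_trip(self, trained, tmp_path):
        save_checkpoint(trained, tmp_path / "ckpt")
        back = load_checkpoint(tmp_path / "ckpt")
        window = np.full((6, 1), 120.0)
        assert np.allclose(predict_horizon(back, window),
                           predict_horizon(trained, window))
        assert back.model_spec == trained.model_spec
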