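"""Stacked recurrent glucose forecaster: build, train, predict.

The reference architecture is a two-layer stacked LSTM — 128 units
emitting the full sequence, a leaky-ReLU layer, dropout, a 64-unit LSTM,
dropout, then a dense linear head whose width equals the prediction
horizon (6 outputs for 30 min, 12 for 60 min on a 5-min grid).  A
single-layer "vanilla" variant and a true bidirectional variant exist
behind flags; bidirectionality is off by default (it lets the encoder
read the window right-to-left as well, which is unusual for pure
forecasting and documented as nonstandard).

Training minimises MSE on standardised targets with Adam (default
learning rate 0.001, batch size 128) and optional early stopping on
validation loss.  All randomness — weight init, batch shuffling, dropout
— flows through one seeded generator, so a seed pins the trained weights
exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .dataset import StandardizerState, invert_standardizer
from .nn import LSTM, Adam, Bidirectional, Dense, Dropout, LeakyReLU, Network


@dataclass(frozen=True)
class ModelSpec:
    """Forecaster architecture hyperparameters."""

    layer1_units: int = 128
    layer2_units: int = 64
    stacked: bool = True
    bidirectional: bool = False
    leaky_relu_slope: float = 0.01
    dropout_rate: float = 0.2
    horizon_len: int = 6  # 6 → 30-min PH, 12 → 60-min PH

    def __post_init__(self) -> None:
        if self.layer1_units < 1 or self.layer2_units < 1:
            raise ValueError("layer units must be positive")
        if self.horizon_len not in (6, 12):
            raise ValueError("horizon_len must be 6 (30 min) or 12 (60 min)")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass(frozen=True)
class TrainingSpec:
    """Optimisation settings."""

    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 100
    early_stop_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0:
            raise ValueError("learning_rate and batch_size must be positive")


def build_forecaster(model_spec: ModelSpec, n_channels: int) -> Network:
    """Assemble the (untrained) layer stack for ``n_channels`` inputs."""
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    s = model_spec
    rec = Bidirectional if s.bidirectional else LSTM
    width = 2 if s.bidirectional else 1
    layers: list = []
    if s.stacked:
        layers += [
            rec(n_channels, s.layer1_units, return_sequences=True),
            LeakyReLU(s.leaky_relu_slope),
            Dropout(s.dropout_rate),
            rec(width * s.layer1_units, s.layer2_units, return_sequences=False),
            Dropout(s.dropout_rate),
            Dense(width * s.layer2_units, s.horizon_len),
        ]
    else:
        layers += [
            rec(n_channels, s.layer1_units, return_sequences=False),
            Dropout(s.dropout_rate),
            Dense(width * s.layer1_units, s.horizon_len),
        ]
    net = Network(layers)
    net.init_weights(np.random.default_rng(0))  # placeholder; train re-seeds
    return net


@dataclass
class TrainedForecaster:
    """A trained network plus everything needed to reuse it."""

    network: Network
    model_spec: ModelSpec
    training_spec: TrainingSpec
    standardizer: StandardizerState
    history: dict[str, list[float]] = field(default_factory=dict)

    @property
    def horizon_len(self) -> int:
        return self.model_spec.horizon_len


def train_forecaster(
    network: Network,
    inputs: np.ndarray,
    outputs: np.ndarray,
    training_spec: TrainingSpec,
    standardizer: StandardizerState,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
    model_spec: ModelSpec | None = None,
) -> TrainedForecaster:
    """Fit the network on standardised windows.

    ``inputs`` is [examples, history, channels] and ``outputs``
    [examples, horizon], both already standardised (targets on the CGM
    channel's scale).  Early stopping restores the best-validation
    weights; without validation data it monitors training loss.
    """
    inputs = np.asarray(inputs, float)
    outputs = np.asarray(outputs, float)
    if inputs.ndim != 3 or outputs.ndim != 2 or len(inputs) != len(outputs):
        raise ValueError(
            f"shape mismatch: inputs {inputs.shape}, outputs {outputs.shape}"
        )
    rng = np.random.default_rng(training_spec.seed)
    network.init_weights(rng)
    optim = Adam(network, lr=training_spec.learning_rate)
    n = len(inputs)
    bs = min(training_spec.batch_size, n)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best = (np.inf, network.get_weights())
    patience_left = training_spec.early_stop_patience

    for epoch in range(training_spec.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, bs):
            batch = order[lo:lo + bs]
            loss = network.loss_and_grad(inputs[batch], outputs[batch])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: check that "
                    "inputs are standardised and try a smaller learning rate"
                )
            optim.step()
            epoch_loss += loss * len(batch)
        history["train_loss"].append(epoch_loss / n)
        if validation is not None and len(validation[0]) > 0:
            vx, vy = validation
            vp = network.forward(vx, train=False)
            monitor = float(np.mean((vp - vy) ** 2))
            history["val_loss"].append(monitor)
        else:
            monitor = history["train_loss"][-1]
        if monitor < best[0] - 1e-12:
            best = (monitor, network.get_weights())
            patience_left = training_spec.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    network.set_weights(best[1])
    return TrainedForecaster(
        network=network,
        model_spec=model_spec or ModelSpec(),
        training_spec=training_spec,
        standardizer=standardizer,
        history=history,
    )


def predict_horizon(model: TrainedForecaster, window: np.ndarray) -> np.ndarray:
    """Predict the next horizon in mg/dL from a raw (unstandardised) window.

    ``window`` is [history, channels] or [examples, history, channels];
    the output has matching leading shape with ``horizon_len`` values,
    inverse-transformed through the attached standardizer's CGM channel.
    """
    from .dataset import apply_standardizer

    window = np.asarray(window, float)
    single = window.ndim == 2
    if single:
        window = window[None]
    if window.ndim != 3 or window.shape[2] != model.standardizer.n_channels:
        raise ValueError(
            f"window shape {window.shape} does not match the standardizer's "
            f"{model.standardizer.n_channels} channel(s)"
        )
    x = apply_standardizer(model.standardizer, window)
    pred = model.network.forward(x, train=False)
    if pred.shape[1] != model.horizon_len:
        raise ValueError("network output does not match spec horizon")
    pred = invert_standardizer(model.standardizer, pred, channel=0)
    return pred[0] if single else pred


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: TrainedForecaster, path) -> None:
    """Save weights (.npz) plus a JSON metadata sidecar (<path>.json)."""
    weights = model.network.get_weights()
    np.savez(path, **weights)
    meta = {
        "model_spec": asdict(model.model_spec),
        "training_spec": asdict(model.training_spec),
        "standardizer": {
            "mean": model.standardizer.mean.tolist(),
            "sd": model.standardizer.sd.tolist(),
        },
        "history": model.history,
    }
    with open(f"{path}.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_checkpoint(path) -> TrainedForecaster:
    with open(f"{path}.json") as fh:
        meta = json.load(fh)
    model_spec = ModelSpec(**meta["model_spec"])
    training_spec = TrainingSpec(**meta["training_spec"])
    standardizer = StandardizerState(
        mean=np.asarray(meta["standardizer"]["mean"]),
        sd=np.asarray(meta["standardizer"]["sd"]),
    )
    net = build_forecaster(model_spec, len(standardizer.mean))
    data = np.load(f"{path}.npz" if not str(path).endswith(".npz") else str(path))
    net.set_weights({k: data[k] for k in data.files})
    return TrainedForecaster(net, model_spec, training_spec, standardizer,
                             meta.get("history", {}))
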