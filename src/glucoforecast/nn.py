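"""Minimal numpy neural-network backend for sequence regression.

Implements exactly the pieces the forecaster needs — LSTM layers (with an
optional bidirectional wrapper), leaky ReLU, inverted dropout, a dense
head, mean-squared-error loss and the Adam optimizer — with explicit
forward/backward passes (backpropagation through time for the LSTM).
Gradients are validated against finite differences in the test suite.

Conventions: batches first; sequence tensors are ``[batch, time,
features]``.  All randomness flows through an injected
``numpy.random.Generator`` so training is reproducible bit-for-bit.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable piecewise form
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base layer: parameters in ``params``, matching grads in ``grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def init_weights(self, rng: np.random.Generator) -> None:  # noqa: D401
        pass

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


class LSTM(Layer):
    """Single LSTM layer; emits the full sequence or only the last state.

    Gate pre-activations ``z = x_t Wx + h_{t-1} Wh + b`` split into
    input/forget/candidate/output blocks; the forget-gate bias starts at
    1 (standard remedy for early forgetting).
    """

    def __init__(self, in_dim: int, units: int, return_sequences: bool) -> None:
        super().__init__()
        self.in_dim, self.units = in_dim, units
        self.return_sequences = return_sequences
        self.params = {
            "Wx": np.zeros((in_dim, 4 * units)),
            "Wh": np.zeros((units, 4 * units)),
            "b": np.zeros(4 * units),
        }
        self._zero_grads()

    def _zero_grads(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def init_weights(self, rng: np.random.Generator) -> None:
        k = 1.0 / np.sqrt(self.units)
        self.params["Wx"] = rng.uniform(-k, k, self.params["Wx"].shape)
        self.params["Wh"] = rng.uniform(-k, k, self.params["Wh"].shape)
        b = np.zeros(4 * self.units)
        b[self.units: 2 * self.units] = 1.0  # forget gate
        self.params["b"] = b

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, T, _ = x.shape
        U = self.units
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((B, U))
        c = np.zeros((B, U))
        self._cache = []
        hs = np.empty((B, T, U))
        for t in range(T):
            z = x[:, t] @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :U])
            f = _sigmoid(z[:, U:2 * U])
            g = np.tanh(z[:, 2 * U:3 * U])
            o = _sigmoid(z[:, 3 * U:])
            c_prev = c
            c = f * c_prev + i * g
            tanh_c = np.tanh(c)
            h_prev = h
            h = o * tanh_c
            hs[:, t] = h
            self._cache.append((x[:, t], h_prev, c_prev, i, f, g, o, c, tanh_c))
        self._x_shape = x.shape
        return hs if self.return_sequences else h

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, T, C = self._x_shape
        U = self.units
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        self._zero_grads()
        dx = np.zeros((B, T, C))
        dh_next = np.zeros((B, U))
        dc_next = np.zeros((B, U))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, c, tanh_c = self._cache[t]
            if self.return_sequences:
                dh = dout[:, t] + dh_next
            else:
                dh = (dout if t == T - 1 else 0.0) + dh_next
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2),
                 do * o * (1 - o)],
                axis=1,
            )
            self.grads["Wx"] += x_t.T @ dz
            self.grads["Wh"] += h_prev.T @ dz
            self.grads["b"] += dz.sum(axis=0)
            dx[:, t] = dz @ Wx.T
            dh_next = dz @ Wh.T
            dc_next = dc * f
        return dx


class Bidirectional(Layer):
    """Run a forward and a reversed-time LSTM; concatenate their features.

    For sequence output the reversed outputs are flipped back before
    concatenation; for last-state output the backward direction
    contributes its final state (computed over the whole reversed
    sequence), as in standard bidirectional wrappers.
    """

    def __init__(self, in_dim: int, units: int, return_sequences: bool) -> None:
        super().__init__()
        self.fwd = LSTM(in_dim, units, return_sequences)
        self.bwd = LSTM(in_dim, units, return_sequences)
        self.return_sequences = return_sequences

    def init_weights(self, rng: np.random.Generator) -> None:
        self.fwd.init_weights(rng)
        self.bwd.init_weights(rng)

    @property
    def n_params(self) -> int:
        return self.fwd.n_params + self.bwd.n_params

    def iter_params(self):
        for name, layer in (("fwd", self.fwd), ("bwd", self.bwd)):
            for key in layer.params:
                yield f"{name}.{key}", layer.params, layer.grads, key

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        yf = self.fwd.forward(x, train)
        yb = self.bwd.forward(x[:, ::-1], train)
        if self.return_sequences:
            yb = yb[:, ::-1]
        return np.concatenate([yf, yb], axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        U = self.fwd.units
        if self.return_sequences:
            df, db = dout[..., :U], dout[..., U:][:, ::-1]
        else:
            df, db = dout[:, :U], dout[:, U:]
        dxf = self.fwd.backward(np.ascontiguousarray(df))
        dxb = self.bwd.backward(np.ascontiguousarray(db))
        return dxf + dxb[:, ::-1]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, self.slope * dout)


class Dropout(Layer):
    """Inverted dropout: active only in training mode."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Dense(Layer):
    """Affine map on the last axis (used as the linear output head)."""

    def __init__(self, in_dim: int, out_dim: int) -> None:
        super().__init__()
        self.in_dim, self.out_dim = in_dim, out_dim
        self.params = {"W": np.zeros((in_dim, out_dim)), "b": np.zeros(out_dim)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def init_weights(self, rng: np.random.Generator) -> None:
        k = 1.0 / np.sqrt(self.in_dim)
        self.params["W"] = rng.uniform(-k, k, (self.in_dim, self.out_dim))
        self.params["b"] = np.zeros(self.out_dim)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Network:
    """A plain layer stack with MSE loss."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def init_weights(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            layer.init_weights(rng)
            if isinstance(layer, Dropout):
                layer.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray,
                      train: bool = True) -> float:
        """Mean-squared error over all horizon positions; sets grads."""
        pred = self.forward(x, train=train)
        diff = pred - y
        loss = float(np.mean(diff**2))
        self.backward(2.0 * diff / diff.size)
        return loss

    def iter_params(self):
        """Yield (unique_name, params_dict, grads_dict, key) triples."""
        for idx, layer in enumerate(self.layers):
            if isinstance(layer, Bidirectional):
                for name, p, g, key in layer.iter_params():
                    yield f"layer{idx}.{name}", p, g, key
            else:
                for key in layer.params:
                    yield f"layer{idx}.{key}", layer.params, layer.grads, key

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def get_weights(self) -> dict[str, np.ndarray]:
        return {name: p[key].copy() for name, p, _, key in self.iter_params()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for name, p, _, key in self.iter_params():
            p[key] = weights[name].copy()


class Adam:
    """Adam optimizer with the usual bias-corrected moment estimates."""

    def __init__(self, net: Network, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.net = net
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(p[key])
                  for name, p, _, key in net.iter_params()}
        self.v = {name: np.zeros_like(p[key])
                  for name, p, _, key in net.iter_params()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, p, g, key in self.net.iter_params():
            grad = g[key]
            self.m[name] = b1 * self.m[name] + (1 - b1) * grad
            self.v[name] = b2 * self.v[name] + (1 - b2) * grad**2
            m_hat = self.m[name] / (1 - b1**self.t)
            v_hat = self.v[name] / (1 - b2**self.t)
            p[key] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
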