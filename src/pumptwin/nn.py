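"""Minimal recurrent-network building blocks for deviation forecasting.

Implements gated memory cells (input/forget/output gates, sigmoid gates,
tanh candidate) and per-timestep dense layers with full backpropagation
through time, vectorised over a batch of sliding windows.  Arrays are
batch-first: (batch, time, features).

This is deliberately small: plain SGD with global-norm gradient
clipping, no dropout, no GPU paths — sized for series of a few hundred
points on one CPU core.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LSTMLayer", "DenseLayer", "SequenceModel", "TrainingDivergedError"]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss or weights become non-finite."""


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LSTMLayer:
    """One recurrent layer of gated memory cells, returning full sequences."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        self.input_size = input_size
        self.hidden_size = hidden_size
        scale = 1.0 / np.sqrt(input_size + hidden_size)
        # gate order: input, forget, candidate, output
        self.W = rng.uniform(-scale, scale, size=(4 * hidden_size, input_size + hidden_size))
        self.b = np.zeros(4 * hidden_size)
        self.b[hidden_size : 2 * hidden_size] = 1.0  # forget-gate bias: remember by default
        self._cache = None

    @property
    def output_size(self) -> int:
        return self.hidden_size

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        H = self.hidden_size
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.empty((B, T, H))
        cache = []
        for t in range(T):
            z = np.concatenate([x[:, t, :], h], axis=1)
            gates = z @ self.W.T + self.b
            i = _sigmoid(gates[:, :H])
            f = _sigmoid(gates[:, H : 2 * H])
            g = np.tanh(gates[:, 2 * H : 3 * H])
            o = _sigmoid(gates[:, 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[:, t, :] = h
            cache.append((z, i, f, g, o, c_prev, tc))
        self._cache = (x.shape, cache)
        return hs

    def backward(self, dout: np.ndarray):
        (B, T, F), cache = self._cache
        H = self.hidden_size
        dW = np.zeros_like(self.W)
        db = np.zeros_like(self.b)
        dx = np.empty((B, T, F))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            z, i, f, g, o, c_prev, tc = cache[t]
            dh = dout[:, t, :] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dgates = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dW += dgates.T @ z
            db += dgates.sum(axis=0)
            dz = dgates @ self.W
            dx[:, t, :] = dz[:, :F]
            dh_next = dz[:, F:]
        return dx, [dW, db]


class DenseLayer:
    """Per-timestep affine layer with tanh or linear activation."""

    def __init__(self, input_size: int, output_size: int, rng: np.random.Generator,
                 activation: str = "tanh"):
        if activation not in ("tanh", "linear"):
            raise ValueError(f"unsupported activation {activation!r}")
        scale = 1.0 / np.sqrt(input_size)
        self.W = rng.uniform(-scale, scale, size=(output_size, input_size))
        self.b = np.zeros(output_size)
        self.activation = activation
        self._cache = None

    @property
    def output_size(self) -> int:
        return self.W.shape[0]

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        pre = x @ self.W.T + self.b
        out = np.tanh(pre) if self.activation == "tanh" else pre
        self._cache = (x, out)
        return out

    def backward(self, dout: np.ndarray):
        x, out = self._cache
        dpre = dout * (1.0 - out**2) if self.activation == "tanh" else dout
        B, T, _ = x.shape
        dpre2 = dpre.reshape(B * T, -1)
        x2 = x.reshape(B * T, -1)
        dW = dpre2.T @ x2
        db = dpre2.sum(axis=0)
        dx = (dpre2 @ self.W).reshape(B, T, -1)
        return dx, [dW, db]


class SequenceModel:
    """A stack of recurrent/dense layers mapping a window to one value.

    Built from a pattern string over {'L', 'D'} (recurrent / dense) with
    ``hidden_units`` units per layer, topped by a linear dense head of
    one unit; the prediction is the head's output at the final timestep.
    """

    def __init__(self, layer_pattern: str, hidden_units: int, input_size: int = 1,
                 seed: int = 0):
        if not layer_pattern or any(ch not in "LD" for ch in layer_pattern):
            raise ValueError(f"layer_pattern must be over 'L'/'D', got {layer_pattern!r}")
        rng = np.random.default_rng(seed)
        self.layers: list = []
        size = input_size
        for ch in layer_pattern:
            if ch == "L":
                layer = LSTMLayer(size, hidden_units, rng)
            else:
                layer = DenseLayer(size, hidden_units, rng, activation="tanh")
            self.layers.append(layer)
            size = layer.output_size
        self.layers.append(DenseLayer(size, 1, rng, activation="linear"))
        self.pattern = layer_pattern
        self.hidden_units = hidden_units
        self._rng = rng

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (batch, window, features) -> predictions (batch,)."""
        out = x
        for layer in self.layers:
            out = layer.forward(out)
        return out[:, -1, 0]

    def train_batch(self, x: np.ndarray, y: np.ndarray, lr: float,
                    clip_norm: float = 1.0) -> float:
        """One SGD step on mean-squared error; returns the batch loss."""
        pred = self.forward(x)
        resid = pred - y
        loss = float(np.mean(resid**2))
        if not np.isfinite(loss):
            raise TrainingDivergedError("non-finite training loss")
        B, T, _ = x.shape
        dout = np.zeros((B, T, 1))
        dout[:, -1, 0] = 2.0 * resid / B
        grads: list[np.ndarray] = []
        d = dout
        for layer in reversed(self.layers):
            d, layer_grads = layer.backward(d)
            grads = layer_grads + grads
        params = [p for layer in self.layers for p in layer.params()]
        total_norm = np.sqrt(sum(float(np.sum(g**2)) for g in grads))
        scale = lr * (clip_norm / total_norm if total_norm > clip_norm else 1.0)
        for p, g in zip(params, grads):
            p -= scale * g
            if not np.all(np.isfinite(p)):
                raise TrainingDivergedError("non-finite weights after update")
        return loss
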