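"""Small numpy neural-network toolkit for the classifier heads.

Implements exactly what the staged classifiers need — affine layers, ReLU,
inverted dropout, batch normalization, a binary-cross-entropy-with-logits
loss, and the Adam optimizer — with explicit forward/backward passes and a
seeded ``numpy.random.Generator`` for all randomness, so training is
bitwise reproducible.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base layer: parameters and gradients are parallel name->array dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = 1.0 / np.sqrt(n_in)
        self.params = {
            "W": rng.normal(0.0, scale, size=(n_in, n_out)),
            "b": np.zeros(n_out),
        }
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._x is not None
        self.grads = {"W": self._x.T @ dout, "b": dout.sum(axis=0)}
        return dout @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout: identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate {rate} outside [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class BatchNorm(Layer):
    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.params = {"gamma": np.ones(dim), "beta": np.zeros(dim)}
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, std = self._xhat, self._std
        self.grads = {
            "gamma": (dout * xhat).sum(axis=0),
            "beta": dout.sum(axis=0),
        }
        dxhat = dout * self.params["gamma"]
        return (dxhat - dxhat.mean(axis=0) - xhat * (dxhat * xhat).mean(axis=0)) / std


class Network:
    """A feed-forward stack ending in a 1-unit logit."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(layer, name) for layer in self.layers for name in layer.params]

    def state(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for name, value in layer.params.items():
                out[f"{i}.{name}"] = value
            if isinstance(layer, BatchNorm):
                out[f"{i}.running_mean"] = layer.running_mean
                out[f"{i}.running_var"] = layer.running_var
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = np.asarray(state[f"{i}.{name}"])
            if isinstance(layer, BatchNorm):
                layer.running_mean = np.asarray(state[f"{i}.running_mean"])
                layer.running_var = np.asarray(state[f"{i}.running_var"])


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy from logits; returns (loss, dlogits)."""
    z = logits.ravel()
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = ((sigmoid(z) - y) / z.size).reshape(logits.shape)
    return loss, grad


class Adam:
    def __init__(
        self,
        network: Network,
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.network = network
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {id(l): {n: np.zeros_like(p) for n, p in l.params.items()} for l in network.layers}
        self.v = {id(l): {n: np.zeros_like(p) for n, p in l.params.items()} for l in network.layers}

    def step(self) -> None:
        self.t += 1
        for layer in self.network.layers:
            for name, param in layer.params.items():
                grad = layer.grads.get(name)
                if grad is None:
                    continue
                m = self.m[id(layer)][name]
                v = self.v[id(layer)][name]
                m[:] = self.beta1 * m + (1 - self.beta1) * grad
                v[:] = self.beta2 * v + (1 - self.beta2) * grad**2
                mhat = m / (1 - self.beta1**self.t)
                vhat = v / (1 - self.beta2**self.t)
                param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
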