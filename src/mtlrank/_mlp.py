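"""Minimal feed-forward network with manual backprop and an Adam optimizer.

The trunk is ``n_layers`` fully connected hidden layers of equal width with a
configurable activation and inverted dropout; the head is a linear layer of
width ``n_out`` emitting the raw per-interval scores.  Gradients are computed
by hand-written reverse-mode passes and are checked against central
differences in the test suite.  Everything is float64 NumPy on the CPU, so a
fixed seed gives a bit-reproducible training trace.
"""

from __future__ import annotations

import numpy as np

_SELU_SCALE = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "selu":
        return _SELU_SCALE * np.where(z > 0, z, _SELU_ALPHA * (np.exp(np.minimum(z, 0.0)) - 1.0))
    if name == "tanh":
        return np.tanh(z)
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    raise ValueError(f"unknown activation {name!r}")


def _act_deriv(name: str, z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return (z > 0).astype(float)
    if name == "selu":
        return _SELU_SCALE * np.where(z > 0, 1.0, _SELU_ALPHA * np.exp(np.minimum(z, 0.0)))
    if name == "tanh":
        return 1.0 - np.tanh(z) ** 2
    if name == "sigmoid":
        s = 1.0 / (1.0 + np.exp(-z))
        return s * (1.0 - s)
    raise ValueError(f"unknown activation {name!r}")


class MLP:
    """Trunk-plus-linear-head multilayer perceptron."""

    def __init__(
        self,
        n_in: int,
        n_out: int,
        n_layers: int = 1,
        width: int = 32,
        activation: str = "relu",
        dropout: float = 0.0,
        seed: int = 0,
    ) -> None:
        if activation not in ("relu", "selu", "tanh", "sigmoid"):
            raise ValueError(f"unknown activation {activation!r}")
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        self.activation = activation
        self.dropout = dropout
        rng = np.random.default_rng(seed)
        dims = [n_in] + [width] * n_layers + [n_out]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            bound = 1.0 / np.sqrt(d_in)
            self.weights.append(rng.uniform(-bound, bound, size=(d_in, d_out)))
            self.biases.append(rng.uniform(-bound, bound, size=d_out))

    @property
    def n_hidden_layers(self) -> int:
        return len(self.weights) - 1

    @property
    def n_params(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)

    def forward(self, X: np.ndarray, train: bool = False, rng=None):
        """Return (output, cache) where cache holds per-layer intermediates."""
        a = np.asarray(X, dtype=float)
        cache = {"inputs": [], "pre": [], "masks": []}
        for li in range(self.n_hidden_layers):
            cache["inputs"].append(a)
            z = a @ self.weights[li] + self.biases[li]
            cache["pre"].append(z)
            a = _act(self.activation, z)
            if train and self.dropout > 0:
                mask = (rng.random(a.shape) >= self.dropout) / (1.0 - self.dropout)
                a = a * mask
                cache["masks"].append(mask)
            else:
                cache["masks"].append(None)
        cache["inputs"].append(a)
        out = a @ self.weights[-1] + self.biases[-1]
        return out, cache

    def predict(self, X: np.ndarray) -> np.ndarray:
        out, _ = self.forward(X, train=False)
        return out

    def backward(self, cache, d_out: np.ndarray):
        """Gradients of a scalar loss given d loss / d output."""
        gW = [np.zeros_like(w) for w in self.weights]
        gb = [np.zeros_like(b) for b in self.biases]
        delta = np.asarray(d_out, dtype=float)
        gW[-1] = cache["inputs"][-1].T @ delta
        gb[-1] = delta.sum(axis=0)
        d_a = delta @ self.weights[-1].T
        for li in range(self.n_hidden_layers - 1, -1, -1):
            if cache["masks"][li] is not None:
                d_a = d_a * cache["masks"][li]
            d_z = d_a * _act_deriv(self.activation, cache["pre"][li])
            gW[li] = cache["inputs"][li].T @ d_z
            gb[li] = d_z.sum(axis=0)
            if li > 0:
                d_a = d_z @ self.weights[li].T
        return gW, gb

    def get_state(self) -> dict:
        return {
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "activation": self.activation,
            "dropout": self.dropout,
        }

    @classmethod
    def from_state(cls, state: dict) -> "MLP":
        weights = [np.asarray(w, dtype=float) for w in state["weights"]]
        obj = cls.__new__(cls)
        obj.activation = state["activation"]
        obj.dropout = state["dropout"]
        obj.weights = weights
        obj.biases = [np.asarray(b, dtype=float) for b in state["biases"]]
        return obj

    def copy_weights(self):
        return [w.copy() for w in self.weights], [b.copy() for b in self.biases]

    def set_weights(self, snapshot) -> None:
        ws, bs = snapshot
        self.weights = [w.copy() for w in ws]
        self.biases = [b.copy() for b in bs]


class Adam:
    """Adam with (coupled) L2 weight decay added to the raw gradient."""

    def __init__(self, lr: float = 1e-3, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self._m, self._v):
            if self.wd:
                g = g + self.wd * p
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
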