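"""Minimal dense-network machinery: layers, Adam, losses, early stopping.

Everything is plain NumPy with explicit backprop so training is
deterministic given a seed and a fixed thread count.
"""

from __future__ import annotations

import numpy as np


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class Dense:
    """Fully connected layer; scaled-uniform fan-in init, zero bias."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / n_in)
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)


class MLP:
    """A stack of Dense layers with per-layer activations.

    ``activations`` has one entry per layer: 'relu', 'tanh' or 'linear'.
    Inverted dropout is applied after every layer except the last when
    ``train=True`` and ``dropout > 0``.
    """

    def __init__(self, sizes, activations, rng: np.random.Generator):
        if len(activations) != len(sizes) - 1:
            raise ValueError("need one activation per layer")
        self.sizes = list(sizes)
        self.activations = list(activations)
        self.layers = [Dense(sizes[i], sizes[i + 1], rng) for i in range(len(sizes) - 1)]

    # -- forward / backward ----------------------------------------------

    def forward(self, x, *, dropout=0.0, rng=None, train=False):
        """Return (output, caches) — caches feed :meth:`backward`."""
        caches = []
        h = np.asarray(x, dtype=float)
        last = len(self.layers) - 1
        for li, (layer, act) in enumerate(zip(self.layers, self.activations)):
            z = h @ layer.W + layer.b
            if act == "relu":
                a = np.maximum(z, 0.0)
            elif act == "tanh":
                a = np.tanh(z)
            elif act == "linear":
                a = z
            else:
                raise ValueError(f"unknown activation {act!r}")
            mask = None
            if train and dropout > 0.0 and li < last:
                if rng is None:
                    raise ValueError("dropout requires an rng")
                mask = (rng.random(a.shape) >= dropout) / (1.0 - dropout)
                a = a * mask
            caches.append((h, z, a, mask))
            h = a
        return h, caches

    def backward(self, caches, grad_out):
        """Return (list of (W_grad, b_grad) per layer, grad wrt input)."""
        grads = [None] * len(self.layers)
        g = grad_out
        for li in range(len(self.layers) - 1, -1, -1):
            h, z, a, mask = caches[li]
            act = self.activations[li]
            if mask is not None:
                g = g * mask
            if act == "relu":
                g = g * (z > 0.0)
            elif act == "tanh":
                g = g * (1.0 - np.tanh(z) ** 2)
            layer = self.layers[li]
            grads[li] = (h.T @ g, g.sum(axis=0))
            g = g @ layer.W.T
        return grads, g

    def __call__(self, x):
        out, _ = self.forward(x)
        return out

    # -- parameter plumbing ----------------------------------------------

    def param_arrays(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.append(layer.W)
            out.append(layer.b)
        return out

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.param_arrays()]

    def set_state(self, state) -> None:
        for p, s in zip(self.param_arrays(), state):
            p[...] = s


class Adam:
    """Adam over a fixed list of parameter arrays, updated in place."""

    def __init__(self, params, lr=5e-5, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


class RMSprop:
    """RMSprop alternative optimizer (config option; Adam is the default)."""

    def __init__(self, params, lr=5e-5, rho=0.9, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.v = [np.zeros_like(p) for p in self.params]

    def step(self, grads) -> None:
        for p, g, v in zip(self.params, grads, self.v):
            v *= self.rho
            v += (1.0 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(v) + self.eps)


def make_optimizer(name: str, params, lr: float):
    if name == "adam":
        return Adam(params, lr=lr)
    if name == "rmsprop":
        return RMSprop(params, lr=lr)
    raise ValueError(f"unknown optimizer {name!r}")


# -- early stopping --------------------------------------------------------


def early_stopping_controller(val_losses, patience: int = 20):
    """Scan a loss curve; return (stop_epoch, best_epoch), 1-indexed.

    Training stops at the first epoch after which ``patience`` consecutive
    epochs have passed without a new strict minimum.  ``stop_epoch`` is
    ``None`` if the horizon ends first.
    """
    if patience < 1:
        raise ValueError("patience must be >= 1")
    best = None
    best_epoch = None
    since = 0
    for epoch, loss in enumerate(val_losses, start=1):
        if best is None or loss < best:
            best, best_epoch, since = loss, epoch, 0
        else:
            since += 1
            if since >= patience:
                return epoch, best_epoch
    return None, best_epoch


class EarlyStopper:
    """Stateful early stopping that snapshots the best parameters."""

    def __init__(self, patience: int = 20):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best_loss = None
        self.best_epoch = None
        self.best_state = None
        self._since = 0
        self.epoch = 0

    def update(self, loss: float, state) -> bool:
        """Record one epoch; return True when training should stop."""
        self.epoch += 1
        if self.best_loss is None or loss < self.best_loss:
            self.best_loss = loss
            self.best_epoch = self.epoch
            self.best_state = [p.copy() for p in state]
            self._since = 0
            return False
        self._since += 1
        return self._since >= self.patience
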