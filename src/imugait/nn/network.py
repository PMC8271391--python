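"""Sequential container, MAE loss and the Adam optimizer."""

from __future__ import annotations

import copy

import numpy as np

from .layers import Layer


def mae_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its subgradient with respect to ``pred``."""
    diff = pred - target
    return float(np.abs(diff).mean()), np.sign(diff) / diff.size


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def trainable_params(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        out = []
        for k, layer in enumerate(self.layers):
            if layer.trainable:
                out.extend((f"{k}.{n}", w, g) for n, w, g in layer.params())
        return out

    def n_trainable(self) -> int:
        return sum(w.size for _, w, _ in self.trainable_params())

    def get_weights(self) -> dict[str, np.ndarray]:
        return {n: w.copy() for n, w, _ in self._all_params()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for n, w, _ in self._all_params():
            w[...] = weights[n]

    def _all_params(self):
        out = []
        for k, layer in enumerate(self.layers):
            out.extend((f"{k}.{n}", w, g) for n, w, g in layer.params())
        return out


class Adam:
    """Adaptive-moment gradient descent over a network's trainable params."""

    def __init__(self, net: Sequential, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {n: np.zeros_like(w) for n, w, _ in net.trainable_params()}
        self.v = copy.deepcopy(self.m)

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for n, w, g in self.net.trainable_params():
            self.m[n] = b1 * self.m[n] + (1 - b1) * g
            self.v[n] = b2 * self.v[n] + (1 - b2) * g * g
            mhat = self.m[n] / (1 - b1**self.t)
            vhat = self.v[n] / (1 - b2**self.t)
            w -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
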