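"""Minimal numpy neural-network core for 1-D time-series classification.

Implements exactly the layers the InceptionTime decoder needs — same-length
1-D convolution, batch normalization, ReLU, stride-1 max pooling, global
pooling over time, a linear head, softmax cross-entropy and Adam — each with
an explicit backward pass.  Backward passes propagate gradients all the way
to the network input, which is what the electrode-contribution (saliency)
analysis consumes.

Array convention: activations are (N, C, T) float64.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Param:
    name: str
    value: np.ndarray
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.grad = np.zeros_like(self.value)


class Layer:
    """Base layer: forward caches what backward needs."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


class Conv1d(Layer):
    """Same-length 1-D convolution (stride 1, zero padding)."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, bias: bool = True) -> None:
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.w = Param("w", rng.normal(0.0, scale, (c_out, c_in, kernel)))
        self.b = Param("b", np.zeros(c_out)) if bias else None
        self._pad_lo = (kernel - 1) // 2
        self._pad_hi = kernel // 2

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (0, 0), (self._pad_lo, self._pad_hi)))
        xw = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        self._xw = xw  # (N, C_in, T, k)
        y = np.tensordot(xw, self.w.value, axes=([1, 3], [1, 2]))  # (N, T, C_out)
        y = np.ascontiguousarray(y.transpose(0, 2, 1))
        if self.b is not None:
            y += self.b.value[None, :, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xw = self._xw
        self.w.grad += np.einsum("not,nctk->ock", dy, xw, optimize=True)
        if self.b is not None:
            self.b.grad += dy.sum(axis=(0, 2))
        n, _, t = dy.shape
        tp = t + self._pad_lo + self._pad_hi
        dxp = np.zeros((n, self.c_in, tp))
        for j in range(self.kernel):
            dxp[:, :, j:j + t] += np.tensordot(
                dy, self.w.value[:, :, j], axes=([1], [0])
            ).transpose(0, 2, 1)
        return dxp[:, :, self._pad_lo:tp - self._pad_hi]

    def params(self) -> list[Param]:
        return [self.w] + ([self.b] if self.b is not None else [])


class BatchNorm1d(Layer):
    """Per-feature-map batch normalization over (N, T)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        self.gamma = Param("gamma", np.ones(c))
        self.beta = Param("beta", np.zeros(c))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        self._train = train
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) * self._istd[None, :, None]
        return (
            self.gamma.value[None, :, None] * self._xhat
            + self.beta.value[None, :, None]
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, istd = self._xhat, self._istd
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2))
        self.beta.grad += dy.sum(axis=(0, 2))
        g = self.gamma.value[None, :, None] * istd[None, :, None]
        if not self._train:
            return dy * g
        m = dy.shape[0] * dy.shape[2]
        dy_sum = dy.sum(axis=(0, 2), keepdims=True)
        dyx_sum = (dy * xhat).sum(axis=(0, 2), keepdims=True)
        return g * (dy - dy_sum / m - xhat * dyx_sum / m)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool1d(Layer):
    """Stride-1, same-length max pooling (pad with -inf)."""

    def __init__(self, kernel: int = 3) -> None:
        self.kernel = kernel
        self._pad_lo = (kernel - 1) // 2
        self._pad_hi = kernel // 2

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (0, 0), (self._pad_lo, self._pad_hi)),
                    constant_values=-np.inf)
        xw = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        self._argmax = xw.argmax(axis=3)  # (N, C, T)
        self._shape = x.shape
        return xw.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, t = self._shape
        tp = t + self._pad_lo + self._pad_hi
        dxp = np.zeros((n * c, tp))
        rows = np.repeat(np.arange(n * c), t)
        cols = (self._argmax + np.arange(t)[None, None, :]).reshape(-1)
        np.add.at(dxp, (rows, cols), dy.reshape(-1))
        return dxp.reshape(n, c, tp)[:, :, self._pad_lo:tp - self._pad_hi]


class GlobalMaxPool(Layer):
    """(N, C, T) -> (N, C) max over time."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._arg = x.argmax(axis=2)
        self._shape = x.shape
        return x.max(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, t = self._shape
        dx = np.zeros((n, c, t))
        ni, ci = np.indices((n, c))
        dx[ni, ci, self._arg] = dy
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._t = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, :, None], self._t, axis=2) / self._t


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        scale = np.sqrt(2.0 / n_in)
        self.w = Param("w", rng.normal(0.0, scale, (n_out, n_in)))
        self.b = Param("b", np.zeros(n_out))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value

    def params(self) -> list[Param]:
        return [self.w, self.b]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray
                  ) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy; returns (loss, dlogits, probs)."""
    probs = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n, probs


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad * p.grad
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
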