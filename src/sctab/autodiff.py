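"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine providing exactly the operations the classifier
architectures need: affine maps, gated linear units, (ghost) batch
normalization, ReLU/sigmoid, dropout, row-wise 1.5-entmax with its exact
vector-Jacobian product, elementwise products, and a fused class-weighted
softmax cross-entropy. Gradients are accumulated through shared parameters
(the shared feature-transformer blocks are applied twice per forward pass),
and every op's backward rule is checked against central finite differences in
the test suite.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .entmax import entmax15 as _entmax15_np
from .entmax import entmax15_vjp

__all__ = [
    "Tensor", "matmul", "add_bias", "mul", "relu", "sigmoid", "glu",
    "dropout", "scale", "add", "narrow", "entmax_rows", "mask_entropy",
    "weighted_softmax_ce", "BatchNorm", "AdamW", "softmax",
]


class Tensor:
    """Array node on the autodiff tape."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(
        self,
        data: np.ndarray,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], tuple[np.ndarray, ...]] | None = None,
        requires_grad: bool = False,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        """Reverse sweep from this (scalar) node."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node.parents:
                    stack.append((p, False))

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node.parents, node._backward(node.grad)):
                if not parent.requires_grad or g is None:
                    continue
                parent.grad = g if parent.grad is None else parent.grad + g

    def zero_grad(self) -> None:
        self.grad = None


def _t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def matmul(x: Tensor, w: Tensor) -> Tensor:
    out = x.data @ w.data
    return Tensor(out, (x, w), lambda g: (g @ w.data.T, x.data.T @ g))


def add_bias(x: Tensor, b: Tensor) -> Tensor:
    return Tensor(x.data + b.data, (x, b), lambda g: (g, g.sum(axis=0)))


def add(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.data + b.data, (a, b), lambda g: (g, g))


def mul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.data * b.data, (a, b), lambda g: (g * b.data, g * a.data))


def scale(x: Tensor, c: float) -> Tensor:
    return Tensor(x.data * c, (x,), lambda g: (g * c,))


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(x.data * mask, (x,), lambda g: (g * mask,))


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    return Tensor(s, (x,), lambda g: (g * s * (1 - s),))


def glu(x: Tensor) -> Tensor:
    """Gated linear unit: split last axis in half, a * sigmoid(b)."""
    d = x.shape[-1] // 2
    a, b = x.data[..., :d], x.data[..., d:]
    s = 1.0 / (1.0 + np.exp(-np.clip(b, -60, 60)))

    def backward(g):
        return (np.concatenate([g * s, g * a * s * (1 - s)], axis=-1),)

    return Tensor(a * s, (x,), backward)


def narrow(x: Tensor, lo: int, hi: int) -> Tensor:
    """Slice columns [lo, hi) of the last axis."""

    def backward(g):
        full = np.zeros_like(x.data)
        full[..., lo:hi] = g
        return (full,)

    return Tensor(x.data[..., lo:hi], (x,), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0:
        return x
    keep = (rng.random(x.shape) >= p) / (1.0 - p)
    return Tensor(x.data * keep, (x,), lambda g: (g * keep,))


def entmax_rows(x: Tensor) -> Tensor:
    """Row-wise exact 1.5-entmax with its analytic vector-Jacobian product."""
    p = _entmax15_np(x.data, axis=-1)
    return Tensor(p, (x,), lambda g: (entmax15_vjp(p, g, axis=-1),))


def mask_entropy(mask: Tensor, eps: float = 1e-15) -> Tensor:
    """Mean over rows of Shannon entropy -sum_j m_j log(m_j + eps)."""
    m = mask.data
    n_rows = m.shape[0]
    ent = -np.sum(m * np.log(m + eps)) / n_rows

    def backward(g):
        return (g * (-(np.log(m + eps) + m / (m + eps))) / n_rows,)

    return Tensor(np.array(ent), (mask,), backward)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_softmax_ce(logits: Tensor, targets: np.ndarray, weights: np.ndarray) -> Tensor:
    """Class-weighted softmax cross-entropy, averaged with weight normalization.

    loss = sum_i w_{y_i} * (-log p_{i,y_i}) / sum_i w_{y_i}
    """
    p = softmax(logits.data)
    n = logits.shape[0]
    w = weights[targets]
    wsum = w.sum()
    logp = np.log(p[np.arange(n), targets] + 1e-300)
    loss = -(w * logp).sum() / wsum

    def backward(g):
        grad = p * w[:, None]
        grad[np.arange(n), targets] -= w
        return (g * grad / wsum,)

    return Tensor(np.array(loss), (logits,), backward)


class BatchNorm:
    """Batch normalization with optional ghost (virtual) batches.

    During training each virtual batch of ``virtual_batch_size`` rows is
    normalized with its own statistics (ghost batch norm, a regularizer for
    large batches); running statistics are tracked with momentum and used at
    evaluation time. ``virtual_batch_size=None`` gives plain batch norm.
    """

    def __init__(self, dim: int, virtual_batch_size: int | None = None, momentum: float = 0.01):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.vbs = virtual_batch_size
        self.momentum = momentum
        self.eps = 1e-5
        self._calibrating = False
        self._calib_count = 0

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]

    def begin_calibration(self) -> None:
        """Reset running statistics; subsequent training-mode passes average
        batch statistics cumulatively instead of with exponential momentum."""
        self.running_mean = np.zeros_like(self.running_mean)
        self.running_var = np.zeros_like(self.running_var)
        self._calibrating = True
        self._calib_count = 0

    def end_calibration(self) -> None:
        self._calibrating = False

    def _update_stats(self, mu: np.ndarray, unbiased_var: np.ndarray) -> None:
        if self._calibrating:
            self._calib_count += 1
            a = 1.0 / self._calib_count
            self.running_mean = (1 - a) * self.running_mean + a * mu
            self.running_var = (1 - a) * self.running_var + a * unbiased_var
        else:
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased_var

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if not training:
            xh = (x.data - self.running_mean) / np.sqrt(self.running_var + self.eps)
            out = xh * self.gamma.data + self.beta.data
            gamma = self.gamma
            denom = np.sqrt(self.running_var + self.eps)

            def backward_eval(g):
                return (g * gamma.data / denom, (g * xh).sum(axis=0), g.sum(axis=0))

            return Tensor(out, (x, self.gamma, self.beta), backward_eval)

        n = x.shape[0]
        vbs = self.vbs or n
        chunks = [(lo, min(lo + vbs, n)) for lo in range(0, n, vbs)]
        xh = np.empty_like(x.data)
        stats = []
        for lo, hi in chunks:
            xc = x.data[lo:hi]
            mu = xc.mean(axis=0)
            var = xc.var(axis=0)
            xh[lo:hi] = (xc - mu) / np.sqrt(var + self.eps)
            stats.append((lo, hi, var))
            m = hi - lo
            self._update_stats(mu, var * (m / max(m - 1, 1)))
        out = xh * self.gamma.data + self.beta.data
        gamma_data = self.gamma.data

        def backward_train(g):
            dx = np.empty_like(g)
            for lo, hi, var in stats:
                gc = g[lo:hi] * gamma_data
                m = hi - lo
                xhc = xh[lo:hi]
                inv = 1.0 / np.sqrt(var + self.eps)
                dx[lo:hi] = inv * (
                    gc - gc.mean(axis=0) - xhc * (gc * xhc).mean(axis=0)
                )
            return (dx, (g * xh).sum(axis=0), g.sum(axis=0))

        return Tensor(out, (x, self.gamma, self.beta), backward_train)


class AdamW:
    """AdamW: Adam moments with decoupled weight decay."""

    def __init__(self, params: list[Tensor], lr: float, weight_decay: float = 0.0,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
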