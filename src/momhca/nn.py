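"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Provides exactly the primitives the integration pipeline trains with:
dense linear layers, batch/layer normalisation, GELU/ELU/ReLU, row-wise
softmax / log-softmax, dropout, and an Adam optimiser with decoupled-style
L2 weight decay. Everything is full-batch and deterministic given a seed;
there is no GPU path and no broadcasting beyond standard NumPy rules.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Linear",
    "BatchNorm1d",
    "Adam",
    "gelu",
    "elu",
    "relu",
    "softmax_rows",
    "log_softmax_rows",
    "dropout",
    "l2_normalize_rows",
    "layer_norm",
    "cross_entropy",
    "mse",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False,
                 _prev: Sequence["Tensor"] = (), _backward: Callable[[], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = _backward
        self._prev = tuple(_prev)

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if id(node) in seen:
                continue
            if expanded:
                seen.add(id(node))
                topo.append(node)
            else:
                stack.append((node, True))
                for p in node._prev:
                    if id(p) not in seen:
                        stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()
        # the backward closures reference their own output node, forming
        # reference cycles; clear them so epoch graphs free by refcount
        for node in topo:
            node._backward = None
            node._prev = ()

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def _bwd():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))
        out._backward = _bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def _bwd():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))
        out._backward = _bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))

        def _bwd():
            if self.requires_grad:
                self._accum(out.grad * p * self.data ** (p - 1))
        out._backward = _bwd
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def _bwd():
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)
        out._backward = _bwd
        return out

    @property
    def T(self):
        out = Tensor(self.data.T, self.requires_grad, (self,))

        def _bwd():
            if self.requires_grad:
                self._accum(out.grad.T)
        out._backward = _bwd
        return out

    # -- reductions / reshaping --------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def _bwd():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())
        out._backward = _bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def rows(self, idx: np.ndarray):
        """Select rows (fancy indexing along axis 0)."""
        idx = np.asarray(idx)
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def _bwd():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)
        out._backward = _bwd
        return out

    def concat(self, other: "Tensor", axis: int = 1):
        other = self._wrap(other)
        out = Tensor(np.concatenate([self.data, other.data], axis=axis),
                     self.requires_grad or other.requires_grad, (self, other))
        n = self.data.shape[axis]

        def _bwd():
            ga, gb = np.split(out.grad, [n], axis=axis)
            if self.requires_grad:
                self._accum(ga)
            if other.requires_grad:
                other._accum(gb)
        out._backward = _bwd
        return out

    # -- elementwise nonlinearities ----------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))

        def _bwd():
            if self.requires_grad:
                self._accum(out.grad * out.data)
        out._backward = _bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def _bwd():
            if self.requires_grad:
                self._accum(out.grad / self.data)
        out._backward = _bwd
        return out

    def detach(self):
        return Tensor(self.data.copy())

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# activations


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), x.requires_grad, (x,))

    def _bwd():
        if x.requires_grad:
            x._accum(out.grad * (x.data > 0))
    out._backward = _bwd
    return out


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    neg = alpha * (np.exp(np.minimum(x.data, 0.0)) - 1.0)
    val = np.where(x.data > 0, x.data, neg)
    out = Tensor(val, x.requires_grad, (x,))

    def _bwd():
        if x.requires_grad:
            x._accum(out.grad * np.where(x.data > 0, 1.0, neg + alpha))
    out._backward = _bwd
    return out


_SQRT2 = math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    from scipy.special import erf

    cdf = 0.5 * (1.0 + erf(x.data / _SQRT2))
    out = Tensor(x.data * cdf, x.requires_grad, (x,))

    def _bwd():
        if x.requires_grad:
            pdf = _INV_SQRT2PI * np.exp(-0.5 * x.data ** 2)
            x._accum(out.grad * (cdf + x.data * pdf))
    out._backward = _bwd
    return out


_ACTIVATIONS: dict[str, Callable[[Tensor], Tensor]] = {
    "relu": relu, "elu": elu, "gelu": gelu, "linear": lambda t: t,
}


def activation(name: str) -> Callable[[Tensor], Tensor]:
    try:
        return _ACTIVATIONS[name]
    except KeyError:
        raise ValueError(f"unknown activation {name!r}") from None


# ---------------------------------------------------------------------------
# fused row-wise ops


def softmax_rows(x: Tensor) -> Tensor:
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(s, x.requires_grad, (x,))

    def _bwd():
        if x.requires_grad:
            g = out.grad
            x._accum(s * (g - (g * s).sum(axis=-1, keepdims=True)))
    out._backward = _bwd
    return out


def log_softmax_rows(x: Tensor) -> Tensor:
    z = x.data - x.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    out = Tensor(z - lse, x.requires_grad, (x,))

    def _bwd():
        if x.requires_grad:
            g = out.grad
            sm = np.exp(out.data)
            x._accum(g - sm * g.sum(axis=-1, keepdims=True))
    out._backward = _bwd
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool = True) -> Tensor:
    if not training or rate <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


def l2_normalize_rows(x: Tensor, eps: float = 1e-12) -> Tensor:
    norm = (x * x).sum(axis=1, keepdims=True) ** 0.5
    return x * ((norm + eps) ** -1.0)


def layer_norm(x: Tensor, gain: Tensor | None = None, bias: Tensor | None = None,
               eps: float = 1e-5) -> Tensor:
    """Row-wise standardisation with optional learnable affine transform."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    y = xc * ((var + eps) ** -0.5)
    if gain is not None:
        y = y * gain
    if bias is not None:
        y = y + bias
    return y


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy over rows of `logits`."""
    labels = np.asarray(labels, dtype=np.int64)
    n = logits.data.shape[0]
    lsm = log_softmax_rows(logits)
    onehot = np.zeros_like(logits.data)
    onehot[np.arange(n), labels] = 1.0
    return -(lsm * Tensor(onehot)).sum() * (1.0 / n)


def mse(a: Tensor, b: Tensor) -> Tensor:
    d = a - b
    return (d * d).mean()


# ---------------------------------------------------------------------------
# layers


class Linear:
    """Affine layer with Glorot-uniform weight initialisation."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        limit = math.sqrt(6.0 / (n_in + n_out))
        self.W = Parameter(rng.uniform(-limit, limit, size=(n_in, n_out)))
        self.b = Parameter(np.zeros(n_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out

    def parameters(self) -> list[Parameter]:
        return [self.W] + ([self.b] if self.b is not None else [])


class BatchNorm1d:
    """Per-feature batch normalisation (batch statistics while training,
    running statistics at inference)."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(n_features))
        self.beta = Parameter(np.zeros(n_features))
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool = True) -> Tensor:
        if training:
            mu = x.mean(axis=0, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=0, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
            y = xc * ((var + self.eps) ** -0.5)
        else:
            y = (x - Tensor(self.running_mean)) * Tensor(
                1.0 / np.sqrt(self.running_var + self.eps))
        return y * self.gamma + self.beta

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]


class Adam:
    """Adam with optional L2 weight decay folded into the gradient."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            p.data -= self.lr * (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)
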