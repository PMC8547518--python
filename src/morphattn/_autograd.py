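"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the attention classifier needs: broadcasted
arithmetic, batched matrix products, reductions, element-wise nonlinearities,
concatenation and a numerically stable binary cross-entropy on logits.
Gradients are accumulated in float64; the engine is deliberately eager and
single-threaded, which keeps forward/backward passes bit-reproducible.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "softmax", "bce_with_logits", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _prev: Iterable["Tensor"] = (),
    ) -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._prev = tuple(_prev)

    # -- helpers ----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def backward() -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def backward() -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * (-1.0)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data / other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def backward() -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.shape))
            if other.requires_grad:
                g = -out.grad * self.data / (other.data ** 2)
                other._accum(_unbroadcast(g, other.shape))

        out._backward = backward
        return out

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor(self.data ** exponent, self.requires_grad, (self,))

        def backward() -> None:
            if self.requires_grad:
                self._accum(out.grad * exponent * self.data ** (exponent - 1))

        out._backward = backward
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def backward() -> None:
            g = out.grad
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        out._backward = backward
        return out

    def swap_last(self) -> "Tensor":
        """Transpose the last two axes."""
        out = Tensor(np.swapaxes(self.data, -1, -2), self.requires_grad, (self,))

        def backward() -> None:
            if self.requires_grad:
                self._accum(np.swapaxes(out.grad, -1, -2))

        out._backward = backward
        return out

    # -- reductions -------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def backward() -> None:
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ---------------------------------------------------

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))

        def backward() -> None:
            if self.requires_grad:
                self._accum(out.grad * out.data)

        out._backward = backward
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def backward() -> None:
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out._backward = backward
        return out

    def leaky_relu(self, slope: float) -> "Tensor":
        mask = np.where(self.data > 0, 1.0, slope)
        out = Tensor(self.data * mask, self.requires_grad, (self,))

        def backward() -> None:
            if self.requires_grad:
                self._accum(out.grad * mask)

        out._backward = backward
        return out

    def relu(self) -> "Tensor":
        return self.leaky_relu(0.0)

    def sigmoid(self) -> "Tensor":
        s = np.where(self.data >= 0,
                     1.0 / (1.0 + np.exp(-np.abs(self.data))),
                     np.exp(-np.abs(self.data)) / (1.0 + np.exp(-np.abs(self.data))))
        out = Tensor(s, self.requires_grad, (self,))

        def backward() -> None:
            if self.requires_grad:
                self._accum(out.grad * s * (1.0 - s))

        out._backward = backward
        return out

    def sqrt(self) -> "Tensor":
        return self ** 0.5

    def reshape(self, *shape: int) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def backward() -> None:
            if self.requires_grad:
                self._accum(out.grad.reshape(self.shape))

        out._backward = backward
        return out

    # -- backprop ---------------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward() -> None:
        pieces = np.split(out.grad, splits, axis=axis)
        for t, g in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(g)

    out._backward = backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Row-stochastic softmax, numerically stabilised by a detached max."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy evaluated on raw logits.

    Uses the log-sum-exp form so the loss never produces NaN for large
    magnitude logits; the backward pass is the closed form (sigmoid(z) - y)/n.
    """
    z = logits.data
    y = np.asarray(targets, dtype=np.float64)
    losses = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(losses.mean(), logits.requires_grad, (logits,))

    def backward() -> None:
        if logits.requires_grad:
            e = np.exp(-np.abs(z))
            s = np.where(z >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
            logits._accum(out.grad * (s - y) / z.size)

    out._backward = backward
    return out


class Adam:
    """Adam with optional L2-coupled weight decay (decay added to the gradient)."""

    def __init__(self, params: Sequence[Tensor], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0) -> None:
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = float(weight_decay)
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
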