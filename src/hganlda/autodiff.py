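"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine sized to this package's needs: dense float64
tensors, the handful of operations the hierarchical attention network
uses (matmul, broadcasting arithmetic, the LeakyReLU/ELU/tanh/sigmoid
nonlinearities, reductions, row gathers, concatenation) and an Adam
optimizer with L2-style weight decay. Gradients are accumulated by a
topological backward sweep; correctness is pinned down by
finite-difference tests.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "take_rows", "Adam", "glorot"]


def _as_array(value) -> np.ndarray:
    return np.asarray(value, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to the operand's shape."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- graph machinery -------------------------------------------------
    @staticmethod
    def as_tensor(value) -> "Tensor":
        return value if isinstance(value, Tensor) else Tensor(value)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = _as_array(grad).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.requires_grad and self.grad is not None:
            self.grad += grad

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other)

        def backward(grad):
            self._accumulate(_unbroadcast(grad, self.shape))
            other._accumulate(_unbroadcast(grad, other.shape))

        return Tensor(self.data + other.data, _parents=(self, other), _backward=backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(grad):
            self._accumulate(-grad)

        return Tensor(-self.data, _parents=(self,), _backward=backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other)

        def backward(grad):
            self._accumulate(_unbroadcast(grad * other.data, self.shape))
            other._accumulate(_unbroadcast(grad * self.data, other.shape))

        return Tensor(self.data * other.data, _parents=(self, other), _backward=backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other)

        def backward(grad):
            self._accumulate(_unbroadcast(grad / other.data, self.shape))
            other._accumulate(
                _unbroadcast(-grad * self.data / (other.data**2), other.shape)
            )

        return Tensor(self.data / other.data, _parents=(self, other), _backward=backward)

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor.as_tensor(other) / self

    def __matmul__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other)
        a, b = self.data, other.data

        def backward(grad):
            if a.ndim == 1 and b.ndim == 1:
                self._accumulate(grad * b)
                other._accumulate(grad * a)
            elif b.ndim == 1:
                self._accumulate(np.outer(grad, b).reshape(a.shape))
                other._accumulate(a.T @ grad)
            elif a.ndim == 1:
                self._accumulate(grad @ b.T)
                other._accumulate(np.outer(a, grad))
            else:
                self._accumulate(grad @ b.T)
                other._accumulate(a.T @ grad)

        return Tensor(a @ b, _parents=(self, other), _backward=backward)

    @property
    def T(self) -> "Tensor":
        def backward(grad):
            self._accumulate(grad.T)

        return Tensor(self.data.T, _parents=(self,), _backward=backward)

    def reshape(self, *shape) -> "Tensor":
        def backward(grad):
            self._accumulate(grad.reshape(self.shape))

        return Tensor(self.data.reshape(*shape), _parents=(self,), _backward=backward)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(grad):
            g = grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims),
            _parents=(self,),
            _backward=backward,
        )

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(count)

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(grad):
            self._accumulate(grad * out_data)

        return Tensor(out_data, _parents=(self,), _backward=backward)

    def log(self) -> "Tensor":
        def backward(grad):
            self._accumulate(grad / self.data)

        return Tensor(np.log(self.data), _parents=(self,), _backward=backward)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward(grad):
            self._accumulate(grad * (1.0 - out_data**2))

        return Tensor(out_data, _parents=(self,), _backward=backward)

    def sigmoid(self) -> "Tensor":
        out_data = np.where(
            self.data >= 0,
            1.0 / (1.0 + np.exp(-np.abs(self.data))),
            np.exp(-np.abs(self.data)) / (1.0 + np.exp(-np.abs(self.data))),
        )

        def backward(grad):
            self._accumulate(grad * out_data * (1.0 - out_data))

        return Tensor(out_data, _parents=(self,), _backward=backward)

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        mask = self.data > 0

        def backward(grad):
            self._accumulate(grad * np.where(mask, 1.0, slope))

        return Tensor(
            np.where(mask, self.data, slope * self.data),
            _parents=(self,),
            _backward=backward,
        )

    def elu(self, alpha: float = 1.0) -> "Tensor":
        mask = self.data > 0
        expm1 = alpha * np.expm1(np.minimum(self.data, 0.0))

        def backward(grad):
            self._accumulate(grad * np.where(mask, 1.0, expm1 + alpha))

        return Tensor(np.where(mask, self.data, expm1), _parents=(self,), _backward=backward)

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient passes through only in the interior."""
        inside = (self.data > lo) & (self.data < hi)

        def backward(grad):
            self._accumulate(grad * inside)

        return Tensor(np.clip(self.data, lo, hi), _parents=(self,), _backward=backward)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along an axis."""
    tensors = [Tensor.as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * grad.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(grad[tuple(sl)])

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _backward=backward,
    )


def take_rows(tensor: Tensor, indices) -> Tensor:
    """Gather rows by integer index (with repeat-safe gradient scatter)."""
    indices = np.asarray(indices, dtype=int)

    def backward(grad):
        if tensor.requires_grad and tensor.grad is not None:
            np.add.at(tensor.grad, indices, grad)

    return Tensor(tensor.data[indices], _parents=(tensor,), _backward=backward)


def glorot(rng: np.random.Generator, *shape: int) -> Tensor:
    """Uniform Glorot/Xavier fan-based initialisation."""
    fan_in = shape[0] if len(shape) > 1 else shape[0]
    fan_out = shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Adam:
    """Adam with decoupled weight decay (AdamW semantics).

    Decay is applied directly to the parameters (``p -= lr * wd * p``)
    rather than added to the gradient: under Adam's per-parameter
    normalisation a coupled L2 term moves every weight toward zero at
    roughly the learning rate regardless of how small the data gradient
    is, which drives the network into the constant-output fixed point
    before it can learn.
    """

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        weight_decay: float = 0.0,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            grad = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay:
                p.data *= 1.0 - self.lr * self.weight_decay
            m *= b1
            m += (1 - b1) * grad
            v *= b2
            v += (1 - b2) * grad**2
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
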