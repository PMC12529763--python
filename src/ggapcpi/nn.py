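"""Reverse-mode automatic differentiation over NumPy arrays.

A minimal define-by-run tape: :class:`Tensor` wraps a float64 ndarray and
records the operations needed to backpropagate.  It provides exactly the
primitives the network requires — dense affine maps, ReLU/sigmoid/tanh,
row softmax, concatenation, segment sum/max over graph edges, gather — plus a
GRU cell and an Adam optimizer.  Everything is deterministic given the numpy
Generator used for initialisation.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _prev: tuple["Tensor", ...] = (),
        name: str | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._prev = _prev
        self.name = name

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar or any-shape) tensor with seed 1."""
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for child in node._prev:
                if id(child) not in visited:
                    stack.append((child, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------- arithmetic
    def _as_tensor(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        other = self._as_tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _backward():
            if self.requires_grad or self._prev:
                self._accumulate(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad or other._prev:
                other._accumulate(_unbroadcast(out.grad, other.data.shape))

        out._backward = _backward
        return out

    def __mul__(self, other) -> "Tensor":
        other = self._as_tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _backward():
            if self.requires_grad or self._prev:
                self._accumulate(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad or other._prev:
                other._accumulate(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = _backward
        return out

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other) -> "Tensor":
        return self + (-self._as_tensor(other))

    __radd__ = __add__
    __rmul__ = __mul__

    def __truediv__(self, scalar: float) -> "Tensor":
        return self * (1.0 / float(scalar))

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def _backward():
            if self.requires_grad or self._prev:
                self._accumulate(out.grad @ other.data.T)
            if other.requires_grad or other._prev:
                other._accumulate(self.data.T @ out.grad)

        out._backward = _backward
        return out

    __matmul__ = matmul

    # ------------------------------------------------------------ activations
    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))

        def _backward():
            self._accumulate(out.grad * (self.data > 0))

        out._backward = _backward
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))

        def _backward():
            self._accumulate(out.grad * s * (1.0 - s))

        out._backward = _backward
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        out = Tensor(t, _prev=(self,))

        def _backward():
            self._accumulate(out.grad * (1.0 - t * t))

        out._backward = _backward
        return out

    def softmax_rows(self) -> "Tensor":
        """Softmax over the last axis (numerically stabilised)."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=-1, keepdims=True)
        out = Tensor(s, _prev=(self,))

        def _backward():
            g = out.grad
            dot = (g * s).sum(axis=-1, keepdims=True)
            self._accumulate(s * (g - dot))

        out._backward = _backward
        return out

    # -------------------------------------------------------------- reshaping
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _backward():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = _backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def _backward():
            self._accumulate(out.grad.reshape(self.data.shape))

        out._backward = _backward
        return out

    def transpose(self) -> "Tensor":
        out = Tensor(self.data.T, _prev=(self,))

        def _backward():
            self._accumulate(out.grad.T)

        out._backward = _backward
        return out

    @property
    def T(self) -> "Tensor":
        return self.transpose()

    def slice_cols(self, start: int, stop: int) -> "Tensor":
        out = Tensor(self.data[:, start:stop], _prev=(self,))

        def _backward():
            g = np.zeros_like(self.data)
            g[:, start:stop] = out.grad
            self._accumulate(g)

        out._backward = _backward
        return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _backward():
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * out.grad.ndim
            idx[axis] = slice(a, b)
            t._accumulate(out.grad[tuple(idx)])

    out._backward = _backward
    return out


def gather_rows(t: Tensor, index: np.ndarray) -> Tensor:
    """Row selection ``t[index]`` (repeats allowed); gradients scatter-add back."""
    index = np.asarray(index, dtype=np.intp)
    out = Tensor(t.data[index], _prev=(t,))

    def _backward():
        g = np.zeros_like(t.data)
        np.add.at(g, index, out.grad)
        t._accumulate(g)

    out._backward = _backward
    return out


def segment_sum(t: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``t`` into ``num_segments`` buckets; empty buckets are zero."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    data = np.zeros((num_segments, t.data.shape[1]), dtype=np.float64)
    np.add.at(data, segment_ids, t.data)
    out = Tensor(data, _prev=(t,))

    def _backward():
        t._accumulate(out.grad[segment_ids])

    out._backward = _backward
    return out


def segment_max(t: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Element-wise max of rows per bucket; empty buckets are zero (the
    empty-neighborhood convention).  Gradients flow to every row attaining the
    maximum (ties share the gradient)."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    data = np.full((num_segments, t.data.shape[1]), -np.inf, dtype=np.float64)
    np.maximum.at(data, segment_ids, t.data)
    empty = ~np.isfinite(data)
    data = np.where(empty, 0.0, data)
    out = Tensor(data, _prev=(t,))

    def _backward():
        is_max = t.data == out.data[segment_ids]
        t._accumulate(np.where(is_max, out.grad[segment_ids], 0.0))

    out._backward = _backward
    return out


# --------------------------------------------------------------------- layers
class Parameter(Tensor):
    def __init__(self, data: np.ndarray, name: str):
        super().__init__(data, requires_grad=True, name=name)


def xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


def linear_params(
    rng: np.random.Generator, name: str, fan_in: int, fan_out: int
) -> dict[str, Parameter]:
    return {
        f"{name}.W": Parameter(xavier(rng, fan_in, fan_out), f"{name}.W"),
        f"{name}.b": Parameter(np.zeros(fan_out), f"{name}.b"),
    }


def linear(x: Tensor, params: dict, name: str) -> Tensor:
    return x @ params[f"{name}.W"] + params[f"{name}.b"]


def gru_cell_params(
    rng: np.random.Generator, name: str, input_dim: int, hidden_dim: int
) -> dict[str, Parameter]:
    """Gated recurrent unit cell: weight_ih (in,3h), weight_hh (h,3h), two biases."""
    return {
        f"{name}.W_ih": Parameter(xavier(rng, input_dim, 3 * hidden_dim), f"{name}.W_ih"),
        f"{name}.W_hh": Parameter(xavier(rng, hidden_dim, 3 * hidden_dim), f"{name}.W_hh"),
        f"{name}.b_ih": Parameter(np.zeros(3 * hidden_dim), f"{name}.b_ih"),
        f"{name}.b_hh": Parameter(np.zeros(3 * hidden_dim), f"{name}.b_hh"),
    }


def gru_cell(x: Tensor, h: Tensor, params: dict, name: str) -> Tensor:
    """One GRU update: r/z gates then candidate state, h' = (1-z)*n + z*h."""
    hidden = params[f"{name}.W_hh"].shape[1] // 3
    gi = x @ params[f"{name}.W_ih"] + params[f"{name}.b_ih"]
    gh = h @ params[f"{name}.W_hh"] + params[f"{name}.b_hh"]
    i_r, i_z, i_n = (gi.slice_cols(k * hidden, (k + 1) * hidden) for k in range(3))
    h_r, h_z, h_n = (gh.slice_cols(k * hidden, (k + 1) * hidden) for k in range(3))
    r = (i_r + h_r).sigmoid()
    z = (i_z + h_z).sigmoid()
    n = (i_n + r * h_n).tanh()
    one = Tensor(np.ones_like(z.data))
    return (one - z) * n + z * h


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity at inference."""
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


class Adam:
    """Adaptive-moment first-order optimizer (bias-corrected)."""

    def __init__(
        self,
        params: Iterable[Parameter],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - Tensor(np.asarray(target, dtype=np.float64))
    return (diff * diff).mean()
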