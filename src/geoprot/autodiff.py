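"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This module provides the differentiable-tensor substrate for the geometric
graph layers, the stub transformer language model, integrated-gradients
attribution and the training loops. It implements exactly the operations
those components need — broadcasted arithmetic, matmul, reductions,
pointwise nonlinearities, gather/segment aggregation for message passing,
and numerically stable softmax/log-softmax — with gradients accumulated by
topological-order backpropagation.

Design notes
------------
* ``Tensor`` wraps a float64 ``ndarray``. Gradients are only *stored* on
  tensors with ``requires_grad=True`` (leaves / parameters and any tensor a
  caller explicitly marks), but they always *flow through* intermediate
  nodes.
* A module-level ``no_grad`` context disables graph recording entirely;
  forward passes inside it are plain NumPy.
* All computation is float64 and single-threaded NumPy, so a fixed seed
  yields bitwise-reproducible training runs.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables graph construction."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing broadcasted axes."""
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
    """A NumPy array plus (optionally) a node in a reverse-mode graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad = self.grad + g

    def backward(self, grad: np.ndarray | None = None):
        """Backpropagate from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node._accumulate(g)
            if node._backward is None:
                continue
            for parent, pg in node._backward(g):
                if pg is None:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, pow_(other, -1.0))
        return mul(self, 1.0 / np.asarray(other, dtype=np.float64))

    def __rtruediv__(self, other):
        return mul(pow_(self, -1.0), other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes if axes else None)

    @property
    def T(self):
        return transpose(self, None)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(isinstance(p, Tensor) for p in parents):
        out._parents = tuple(p for p in parents if isinstance(p, Tensor))
        out._backward = backward
    return out


# ------------------------------------------------------------------ basic ops
def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def backward(g):
        return ((a, _unbroadcast(g, a.data.shape)), (b, _unbroadcast(g, b.data.shape)))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def backward(g):
        return (
            (a, _unbroadcast(g * b.data, a.data.shape)),
            (b, _unbroadcast(g * a.data, b.data.shape)),
        )

    return _make(data, (a, b), backward)


def pow_(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    data = a.data ** exponent

    def backward(g):
        return ((a, g * exponent * a.data ** (exponent - 1.0)),)

    return _make(data, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return ((a, _unbroadcast(ga, a.data.shape)), (b, _unbroadcast(gb, b.data.shape)))

    return _make(data, (a, b), backward)


def sum_(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return ((a, np.broadcast_to(g, a.data.shape).copy()),)

    return _make(data, (a,), backward)


def mean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    data = a.data.reshape(shape)

    def backward(g):
        return ((a, g.reshape(a.data.shape)),)

    return _make(data, (a,), backward)


def transpose(a, axes=None) -> Tensor:
    a = as_tensor(a)
    data = a.data.transpose(axes)

    def backward(g):
        inv = None if axes is None else np.argsort(axes)
        return ((a, g.transpose(inv)),)

    return _make(data, (a,), backward)


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)
    data = a.data[idx]

    def backward(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        return ((a, full),)

    return _make(data, (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, pieces))

    return _make(data, tensors, backward)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        pieces = np.split(g, len(tensors), axis=axis)
        return tuple((t, np.squeeze(p, axis=axis)) for t, p in zip(tensors, pieces))

    return _make(data, tensors, backward)


# ------------------------------------------------------------- nonlinearities
def exp(a) -> Tensor:
    a = as_tensor(a)
    data = np.exp(a.data)

    def backward(g):
        return ((a, g * data),)

    return _make(data, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)
    data = np.log(a.data)

    def backward(g):
        return ((a, g / a.data),)

    return _make(data, (a,), backward)


def tanh(a) -> Tensor:
    a = as_tensor(a)
    data = np.tanh(a.data)

    def backward(g):
        return ((a, g * (1.0 - data * data)),)

    return _make(data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    data = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500)))

    def backward(g):
        return ((a, g * data * (1.0 - data)),)

    return _make(data, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    data = np.maximum(a.data, 0.0)

    def backward(g):
        return ((a, g * (a.data > 0.0)),)

    return _make(data, (a,), backward)


def leaky_relu(a, negative_slope: float = 0.2) -> Tensor:
    a = as_tensor(a)
    data = np.where(a.data > 0.0, a.data, negative_slope * a.data)

    def backward(g):
        return ((a, g * np.where(a.data > 0.0, 1.0, negative_slope)),)

    return _make(data, (a,), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * data).sum(axis=axis, keepdims=True)
        return ((a, data * (g - dot)),)

    return _make(data, (a,), backward)


def log_softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    data = shifted - lse

    def backward(g):
        sm = np.exp(data)
        return ((a, g - sm * g.sum(axis=axis, keepdims=True)),)

    return _make(data, (a,), backward)


# ---------------------------------------------------------- geometry-specific
def vecnorm(v, axis: int = -1, keepdims: bool = False, eps: float = 1e-8) -> Tensor:
    """Euclidean norm along ``axis`` with a smoothing epsilon inside the sqrt.

    The epsilon keeps the gradient finite at zero vectors, which occur for the
    flagged-undefined direction features at chain termini.
    """
    v = as_tensor(v)
    sq = (v.data * v.data).sum(axis=axis, keepdims=True)
    n = np.sqrt(sq + eps)
    data = n if keepdims else np.squeeze(n, axis=axis)

    def backward(g):
        g = np.asarray(g)
        if not keepdims:
            g = np.expand_dims(g, axis)
        return ((v, g * v.data / n),)

    return _make(data, (v,), backward)


def vecmap(v, w) -> Tensor:
    """Linear map over the vector-count axis: ``out[n,h,:] = sum_k w[h,k] v[n,k,:]``.

    ``v`` has shape (..., K, 3) and ``w`` shape (H, K); the spatial axis is
    untouched, so the operation commutes with rotations applied to the last
    axis — the source of GVP equivariance.
    """
    v, w = as_tensor(v), as_tensor(w)
    data = np.einsum("hk,...kd->...hd", w.data, v.data)

    def backward(g):
        gv = np.einsum("hk,...hd->...kd", w.data, g)
        h, k = w.data.shape
        gw = np.tensordot(g.reshape(-1, h, 3), v.data.reshape(-1, k, 3),
                          axes=([0, 2], [0, 2]))
        return ((v, gv), (w, gw))

    return _make(data, (v, w), backward)


# ------------------------------------------------------------ graph gathering
def take_rows(a, index: np.ndarray) -> Tensor:
    """Gather rows along axis 0 (edge-source lookup)."""
    a = as_tensor(a)
    index = np.asarray(index, dtype=np.intp)
    data = a.data[index]

    def backward(g):
        full = np.zeros_like(a.data)
        np.add.at(full, index, g)
        return ((a, full),)

    return _make(data, (a,), backward)


def segment_sum(a, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``a`` into ``num_segments`` buckets (message aggregation)."""
    a = as_tensor(a)
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    data = np.zeros((num_segments,) + a.data.shape[1:], dtype=np.float64)
    np.add.at(data, segment_ids, a.data)

    def backward(g):
        return ((a, g[segment_ids]),)

    return _make(data, (a,), backward)


def segment_mean(a, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    counts = np.bincount(np.asarray(segment_ids), minlength=num_segments).astype(np.float64)
    counts = np.maximum(counts, 1.0)
    total = segment_sum(a, segment_ids, num_segments)
    shape = (num_segments,) + (1,) * (total.ndim - 1)
    return mul(total, (1.0 / counts).reshape(shape))


def dropout(a, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    a = as_tensor(a)
    if not training or rate <= 0.0:
        return a
    mask = (rng.random(a.data.shape) >= rate) / (1.0 - rate)
    return mul(a, mask)


# ------------------------------------------------------------------- modules
class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Parameter container with recursive traversal, pytorch-style."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        seen: set[int] = set()
        self._collect(out, seen)
        return out

    def _collect(self, out: list, seen: set):
        for value in vars(self).values():
            self._collect_value(value, out, seen)

    @staticmethod
    def _collect_value(value, out, seen):
        if isinstance(value, Parameter):
            if id(value) not in seen:
                seen.add(id(value))
                out.append(value)
        elif isinstance(value, Module):
            value._collect(out, seen)
        elif isinstance(value, (list, tuple)):
            for v in value:
                Module._collect_value(v, out, seen)
        elif isinstance(value, dict):
            for v in value.values():
                Module._collect_value(v, out, seen)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]):
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError(f"state has {len(state)} arrays, module has {len(params)}")
        for p, arr in zip(params, state):
            if p.data.shape != arr.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {arr.shape}")
            p.data = np.array(arr, dtype=np.float64)


class Linear(Module):
    """Dense layer with Glorot-uniform initialisation."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        limit = np.sqrt(6.0 / (in_features + out_features))
        self.weight = Parameter(rng.uniform(-limit, limit, size=(in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = matmul(x, self.weight)
        if self.bias is not None:
            out = add(out, self.bias)
        return out


class LayerNorm(Module):
    """Layer normalisation over the last axis with learnable scale/shift."""

    def __init__(self, width: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(width))
        self.beta = Parameter(np.zeros(width))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = mean(x, axis=-1, keepdims=True)
        centered = x - mu
        var = mean(mul(centered, centered), axis=-1, keepdims=True)
        inv = pow_(add(var, self.eps), -0.5)
        return add(mul(mul(centered, inv), self.gamma), self.beta)


class Adam:
    """Adam optimizer; parameters with ``requires_grad=False`` are skipped."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if not p.requires_grad or p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
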