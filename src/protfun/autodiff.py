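"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Scalar-loss backprop through the handful of dense ops the model needs:
broadcast arithmetic, 2-D matmul, axis reductions, pointwise
nonlinearities, concatenation/stacking, causal shifts, row gathers and
the two graph-mixing contractions. Everything is float64; gradients are
exact up to floating point (see the finite-difference tests).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "as_tensor", "concatenate", "stack", "shift_rows",
    "take_rows", "mix_function_axis", "mix_protein_axis",
    "matrix_powers", "dropout", "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A NumPy array plus the tape bookkeeping for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward = None

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:  # iterative DFS; deep DCC graphs overflow recursion
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            pending = [p for p in node._parents if id(p) not in seen]
            if pending:
                stack.extend(pending)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # -- operators -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    # convenience method forms
    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape)

    @property
    def T(self):
        return transpose(self)

    def sigmoid(self):
        return sigmoid(self)

    def relu(self):
        return relu(self)

    def exp(self):
        return texp(self)

    def log(self):
        return tlog(self)

    def abs(self):
        return tabs(self)

    def softplus(self):
        return softplus(self)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _wire(out: Tensor, parents: tuple, backward) -> Tensor:
    out.requires_grad = any(p.requires_grad for p in parents)
    out._parents = parents
    out._backward = backward
    return out


# ---------------------------------------------------------------------
# primitive ops
# ---------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data + b.data)

    def bw():
        a.grad += _unbroadcast(out.grad, a.data.shape)
        b.grad += _unbroadcast(out.grad, b.data.shape)

    return _wire(out, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data * b.data)

    def bw():
        a.grad += _unbroadcast(out.grad * b.data, a.data.shape)
        b.grad += _unbroadcast(out.grad * a.data, b.data.shape)

    return _wire(out, (a, b), bw)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data / b.data)

    def bw():
        a.grad += _unbroadcast(out.grad / b.data, a.data.shape)
        b.grad += _unbroadcast(-out.grad * a.data / (b.data ** 2), b.data.shape)

    return _wire(out, (a, b), bw)


def matmul(a, b) -> Tensor:
    """2-D @ 2-D matrix product."""
    a, b = as_tensor(a), as_tensor(b)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("matmul expects 2-D operands; reshape first")
    out = Tensor(a.data @ b.data)

    def bw():
        a.grad += out.grad @ b.data.T
        b.grad += a.data.T @ out.grad

    return _wire(out, (a, b), bw)


def last_linear(x, w) -> Tensor:
    """Contract the last axis of an N-D tensor with a 2-D weight matrix."""
    x, w = as_tensor(x), as_tensor(w)
    out = Tensor(np.tensordot(x.data, w.data, axes=(-1, 0)))

    def bw():
        x.grad += np.tensordot(out.grad, w.data.T, axes=(-1, 0))
        flat_x = x.data.reshape(-1, x.data.shape[-1])
        flat_g = out.grad.reshape(-1, w.data.shape[1])
        w.grad += flat_x.T @ flat_g

    return _wire(out, (x, w), bw)


def transpose(a, axes=None) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.transpose(a.data, axes))

    def bw():
        inv = None if axes is None else np.argsort(axes)
        a.grad += np.transpose(out.grad, inv)

    return _wire(out, (a,), bw)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data.reshape(shape))

    def bw():
        a.grad += out.grad.reshape(a.data.shape)

    return _wire(out, (a,), bw)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims))

    def bw():
        g = out.grad
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a.grad += np.broadcast_to(g, a.data.shape)

    return _wire(out, (a,), bw)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def _stable_logistic(x: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore", invalid="ignore"):
        return np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)),
                        np.exp(np.minimum(x, 0.0)) / (1.0 + np.exp(np.minimum(x, 0.0))))


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    s = _stable_logistic(a.data)
    out = Tensor(s)

    def bw():
        a.grad += out.grad * s * (1.0 - s)

    return _wire(out, (a,), bw)


def relu(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.maximum(a.data, 0.0))

    def bw():
        a.grad += out.grad * (a.data > 0)

    return _wire(out, (a,), bw)


def texp(a) -> Tensor:
    a = as_tensor(a)
    e = np.exp(a.data)
    out = Tensor(e)

    def bw():
        a.grad += out.grad * e

    return _wire(out, (a,), bw)


def tlog(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.log(a.data))

    def bw():
        a.grad += out.grad / a.data

    return _wire(out, (a,), bw)


def tabs(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.abs(a.data))

    def bw():
        a.grad += out.grad * np.sign(a.data)

    return _wire(out, (a,), bw)


def softplus(a) -> Tensor:
    """log(1 + exp(a)), overflow-safe."""
    a = as_tensor(a)
    out = Tensor(np.maximum(a.data, 0.0) + np.log1p(np.exp(-np.abs(a.data))))

    def bw():
        a.grad += out.grad * _stable_logistic(a.data)

    return _wire(out, (a,), bw)


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * out.grad.ndim
            idx[axis] = slice(lo, hi)
            t.grad += out.grad[tuple(idx)]

    return _wire(out, tuple(tensors), bw)


def stack(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis))

    def bw():
        for i, t in enumerate(tensors):
            t.grad += np.take(out.grad, i, axis=axis)

    return _wire(out, tuple(tensors), bw)


def shift_rows(a, offset: int) -> Tensor:
    """Causal shift along axis 0: out[t] = a[t - offset], zero-filled."""
    a = as_tensor(a)
    if offset < 0:
        raise ValueError("offset must be >= 0")
    data = np.zeros_like(a.data)
    if offset == 0:
        data[...] = a.data
    elif offset < a.data.shape[0]:
        data[offset:] = a.data[:-offset]
    out = Tensor(data)

    def bw():
        if offset == 0:
            a.grad += out.grad
        elif offset < a.data.shape[0]:
            a.grad[:-offset] += out.grad[offset:]

    return _wire(out, (a,), bw)


def take_rows(a, indices) -> Tensor:
    a = as_tensor(a)
    indices = np.asarray(indices, dtype=int)
    out = Tensor(a.data[indices])

    def bw():
        np.add.at(a.grad, indices, out.grad)

    return _wire(out, (a,), bw)


def mix_function_axis(m, x) -> Tensor:
    """out[i, p, c] = sum_i' m[i, i'] * x[i', p, c]."""
    m, x = as_tensor(m), as_tensor(x)
    out = Tensor(np.tensordot(m.data, x.data, axes=(1, 0)))

    def bw():
        m.grad += np.tensordot(out.grad, x.data, axes=([1, 2], [1, 2]))
        x.grad += np.tensordot(m.data.T, out.grad, axes=(1, 0))

    return _wire(out, (m, x), bw)


def mix_protein_axis(m, x) -> Tensor:
    """out[f, p, c] = sum_p' m[p, p'] * x[f, p', c]."""
    m, x = as_tensor(m), as_tensor(x)
    out = Tensor(np.einsum("pq,fqc->fpc", m.data, x.data))

    def bw():
        m.grad += np.einsum("fpc,fqc->pq", out.grad, x.data)
        x.grad += np.einsum("pq,fpc->fqc", m.data, out.grad)

    return _wire(out, (m, x), bw)


def matrix_powers(t, n: int) -> list:
    """[t^1, ..., t^n] with gradient flow through every product."""
    t = as_tensor(t)
    powers = [t]
    for _ in range(n - 1):
        powers.append(matmul(powers[-1], t))
    return powers


def dropout(t: Tensor, rate: float, rng: np.random.Generator,
            train: bool) -> Tensor:
    if not train or rate <= 0.0:
        return t
    mask = (rng.random(t.data.shape) >= rate) / (1.0 - rate)
    return mul(t, Tensor(mask))


class Adam:
    """Adaptive-moment gradient descent over a dict of parameter Tensors."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1 ** self.t)
            vhat = self.v[k] / (1 - self.beta2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
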