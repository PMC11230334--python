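"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the encoder zoo needs: broadcast arithmetic,
(batched) matrix products, the usual pointwise nonlinearities, reductions,
slicing and concatenation.  Gradients are accumulated by a topological sweep
over the recorded tape.  ``Parameter`` marks trainable leaves; ``Adam``
updates them.

Design notes
------------
* Shapes follow numpy broadcasting; ``_unbroadcast`` folds gradients back to
  the leaf shape.
* The tape is per-``backward`` call: graphs are rebuilt every step, which is
  the natural fit for variable-length recurrent unrolling.
* Everything is float64 for bit-stable, platform-independent test behaviour.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "as_tensor",
    "concat",
    "log",
    "exp",
    "tanh",
    "sigmoid",
    "relu",
    "sqrt",
    "clip",
    "maximum_scalar",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes numpy broadcasting introduced."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the closure that backpropagates into its parents."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # numpy defers binary ops to us

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: recurrent graphs exceed recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data + other.data,
            self.requires_grad or other.requires_grad,
            parents=(self, other),
        )

        def backward(g):
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data * other.data,
            self.requires_grad or other.requires_grad,
            parents=(self, other),
        )

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * other.data)
            if other.requires_grad:
                other._accumulate(g * self.data)

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data / other.data,
            self.requires_grad or other.requires_grad,
            parents=(self, other),
        )

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / other.data)
            if other.requires_grad:
                other._accumulate(-g * self.data / (other.data**2))

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, self.requires_grad, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data @ other.data,
            self.requires_grad or other.requires_grad,
            parents=(self, other),
        )

        def backward(g):
            a, b = self.data, other.data
            g = np.asarray(g)
            if self.requires_grad:
                if b.ndim == 1:
                    ga = g * b if a.ndim == 1 else g[..., None] * b
                else:
                    ga = g @ np.swapaxes(b, -1, -2)
                self._accumulate(_unbroadcast(np.asarray(ga), a.shape))
            if other.requires_grad:
                if a.ndim == 1:
                    gb = g * a if b.ndim == 1 else np.einsum("d,...k->...dk", a, g)
                elif b.ndim == 1:
                    gb = (a * g[..., None]).sum(axis=tuple(range(a.ndim - 1)))
                else:
                    gb = np.swapaxes(a, -1, -2) @ g
                other._accumulate(_unbroadcast(np.asarray(gb), b.shape))

        out._backward = backward
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], self.requires_grad, parents=(self,))
        basic = isinstance(key, (int, slice)) or (
            isinstance(key, tuple) and all(isinstance(k, (int, slice)) for k in key)
        )

        def backward(g):
            if self.requires_grad:
                if self.grad is None:
                    self.grad = np.zeros_like(self.data)
                if basic:  # basic slices never alias, += suffices
                    self.grad[key] += g
                else:
                    np.add.at(self.grad, key, g)

        out._backward = backward
        return out

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = backward
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, parents=(self,))

        def backward(g):
            if self.requires_grad:
                g = np.asarray(g)
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ------------------------------------------------------------------ functions

def _pointwise(x: Tensor, value: np.ndarray, dvalue: np.ndarray) -> Tensor:
    out = Tensor(value, x.requires_grad, parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * dvalue)

    out._backward = backward
    return out


def log(x):
    if not isinstance(x, Tensor):
        return np.log(x)
    return _pointwise(x, np.log(x.data), 1.0 / x.data)


def exp(x):
    if not isinstance(x, Tensor):
        return np.exp(x)
    v = np.exp(x.data)
    return _pointwise(x, v, v)


def tanh(x):
    if not isinstance(x, Tensor):
        return np.tanh(x)
    v = np.tanh(x.data)
    return _pointwise(x, v, 1.0 - v**2)


def sigmoid(x):
    if not isinstance(x, Tensor):
        return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))
    v = 1.0 / (1.0 + np.exp(-x.data))
    return _pointwise(x, v, v * (1.0 - v))


def relu(x):
    if not isinstance(x, Tensor):
        return np.maximum(x, 0.0)
    return _pointwise(x, np.maximum(x.data, 0.0), (x.data > 0).astype(np.float64))


def sqrt(x):
    if not isinstance(x, Tensor):
        return np.sqrt(x)
    v = np.sqrt(x.data)
    return _pointwise(x, v, 0.5 / v)


def clip(x, lo: float, hi: float):
    """Clamp values; gradient flows only through the unclipped region."""
    if not isinstance(x, Tensor):
        return np.clip(x, lo, hi)
    mask = ((x.data >= lo) & (x.data <= hi)).astype(np.float64)
    return _pointwise(x, np.clip(x.data, lo, hi), mask)


def maximum_scalar(x, c: float):
    """max(x, c) elementwise; at the tie the gradient goes to x (subgradient)."""
    if not isinstance(x, Tensor):
        return np.maximum(x, c)
    mask = (x.data >= c).astype(np.float64)
    return _pointwise(x, np.maximum(x.data, c), mask)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        any(t.requires_grad for t in tensors),
        parents=tuple(tensors),
    )
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    out._backward = backward
    return out


# ------------------------------------------------------------------ optimizer


class Adam:
    """Adam with the standard bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, params, lr: float = 0.005, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
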