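"""Minimal reverse-mode automatic differentiation over numpy arrays.

The trainable pieces of the detector (encoders, the concept-enhancement
block, the scale factor, the ROI heads) are small dense networks, so a
compact tape-based engine is sufficient.  Every differentiable operation
builds a node holding its parents and a closure that accumulates the
vector-Jacobian product into each parent's ``grad`` buffer; ``backward``
walks the tape in reverse topological order.

All arrays are float64.  Broadcasting in ``+ - * /`` is supported; the
backward pass sums gradients over broadcast axes.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an autograd tape.

    Parameters
    ----------
    data:
        Array-like; copied to float64.
    requires_grad:
        Whether gradients should be accumulated for this leaf.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # keep numpy from hijacking reflected ops

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def back(g, a=self, b=other):
            a._accum(_unbroadcast(g, a.data.shape))
            b._accum(_unbroadcast(g, b.data.shape))

        return self._node(self.data + other.data, (self, other), back)

    __radd__ = __add__

    def __neg__(self):
        return self._node(-self.data, (self,), lambda g, a=self: a._accum(-g))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def back(g, a=self, b=other):
            a._accum(_unbroadcast(g * b.data, a.data.shape))
            b._accum(_unbroadcast(g * a.data, b.data.shape))

        return self._node(self.data * other.data, (self, other), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def back(g, a=self, b=other):
            a._accum(_unbroadcast(g / b.data, a.data.shape))
            b._accum(_unbroadcast(-g * a.data / b.data**2, b.data.shape))

        return self._node(self.data / other.data, (self, other), back)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        def back(g, a=self):
            a._accum(g * p * a.data ** (p - 1))

        return self._node(self.data**p, (self,), back)

    def __matmul__(self, other):
        other = self._lift(other)

        def back(g, a=self, b=other):
            a._accum(g @ b.data.T)
            b._accum(a.data.T @ g)

        return self._node(self.data @ other.data, (self, other), back)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def back(g, a=self, d=out_data):
            a._accum(g * d)

        return self._node(out_data, (self,), back)

    def log(self):
        def back(g, a=self):
            a._accum(g / a.data)

        return self._node(np.log(self.data), (self,), back)

    def tanh(self):
        out_data = np.tanh(self.data)

        def back(g, a=self, t=out_data):
            a._accum(g * (1.0 - t**2))

        return self._node(out_data, (self,), back)

    def relu(self):
        mask = self.data > 0

        def back(g, a=self, m=mask):
            a._accum(g * m)

        return self._node(self.data * mask, (self,), back)

    def abs(self):
        sign = np.sign(self.data)

        def back(g, a=self, s=sign):
            a._accum(g * s)

        return self._node(np.abs(self.data), (self,), back)

    def sqrt(self):
        return self**0.5

    # -- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def back(g, a=self):
            if axis is None:
                a._accum(np.full_like(a.data, 1.0) * g)
            else:
                ge = np.asarray(g)
                if not keepdims:
                    ge = np.expand_dims(ge, axis)
                a._accum(np.broadcast_to(ge, a.data.shape).copy())

        return self._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), back)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def reshape(self, *shape):
        def back(g, a=self):
            a._accum(np.asarray(g).reshape(a.data.shape))

        return self._node(self.data.reshape(*shape), (self,), back)

    @property
    def T(self):
        def back(g, a=self):
            a._accum(np.asarray(g).T)

        return self._node(self.data.T, (self,), back)

    def __getitem__(self, idx):
        def back(g, a=self, i=idx):
            buf = np.zeros_like(a.data)
            np.add.at(buf, i, g)
            a._accum(buf)

        return self._node(self.data[idx], (self,), back)

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = 0) -> "Tensor":
        tensors = [Tensor._lift(t) for t in tensors]
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def back(g, ts=tensors, sp=splits, ax=axis):
            for t, piece in zip(ts, np.split(np.asarray(g), sp, axis=ax)):
                t._accum(piece)

        return Tensor._node(
            np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), back
        )

    # -- stabilised softmax ---------------------------------------------------
    def softmax(self, axis: int = -1) -> "Tensor":
        """Row softmax with max-subtraction; the shift is a detached constant."""
        shift = Tensor(self.data.max(axis=axis, keepdims=True))
        e = (self - shift).exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis: int = -1) -> "Tensor":
        shift = Tensor(self.data.max(axis=axis, keepdims=True))
        z = self - shift
        return z - z.exp().sum(axis=axis, keepdims=True).log()

    # -- backward -------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (a scalar unless ``grad`` is given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A leaf tensor that is always trainable."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def zero_grads(params) -> None:
    for p in params:
        p.grad = None


def sgd_step(params, lr: float, max_grad_norm: float | None = None) -> None:
    """In-place vanilla gradient-descent update; missing grads are skipped.

    ``max_grad_norm`` rescales each parameter's gradient to that norm when
    exceeded (per-parameter clipping).
    """
    for p in params:
        if p.grad is not None:
            g = p.grad
            if max_grad_norm is not None:
                n = float(np.linalg.norm(g))
                if n > max_grad_norm:
                    g = g * (max_grad_norm / n)
            p.data -= lr * g


def numeric_grad(fn, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient of scalar ``fn`` at ``x``.

    The independent oracle for every analytic gradient in the package.
    """
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = fn(x)
        flat[i] = orig - eps
        fm = fn(x)
        flat[i] = orig
        gf[i] = (fp - fm) / (2 * eps)
    return g
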