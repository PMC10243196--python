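"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The package trains small convolutional networks on the CPU; this module
provides the tensor/graph machinery those networks are written against.
Arrays are kept in float64 throughout — the problem sizes are small and
double precision keeps the finite-difference gradient checks tight.

Only the operations the networks actually use are implemented.  Every
backward rule is validated against central finite differences in the test
suite, which is the authoritative check on this module.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack_sum"]


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float64, copy=False)
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array plus the graph edges needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        # parents: sequence of (Tensor, fn) where fn maps out-grad -> parent-grad
        self._parents = tuple(parents)

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph ----------------------------------------------------------------
    @staticmethod
    def _make(data, parents) -> "Tensor":
        parents = [(p, fn) for p, fn in parents if p.requires_grad or p._parents]
        if parents:
            return Tensor(data, requires_grad=True, parents=parents)
        return Tensor(data)

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # topological order over the graph
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
            for p, _ in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): _as_array(grad)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            for p, fn in node._parents:
                pg = fn(g)
                if pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        o = self._coerce(other)
        out = self.data + o.data
        return Tensor._make(out, [
            (self, lambda g: _unbroadcast(g, self.data.shape)),
            (o, lambda g: _unbroadcast(g, o.data.shape)),
        ])

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, [(self, lambda g: -g)])

    def __sub__(self, other):
        o = self._coerce(other)
        out = self.data - o.data
        return Tensor._make(out, [
            (self, lambda g: _unbroadcast(g, self.data.shape)),
            (o, lambda g: _unbroadcast(-g, o.data.shape)),
        ])

    def __rsub__(self, other):
        return self._coerce(other) - self

    def __mul__(self, other):
        o = self._coerce(other)
        out = self.data * o.data
        return Tensor._make(out, [
            (self, lambda g: _unbroadcast(g * o.data, self.data.shape)),
            (o, lambda g: _unbroadcast(g * self.data, o.data.shape)),
        ])

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._coerce(other)
        out = self.data / o.data
        return Tensor._make(out, [
            (self, lambda g: _unbroadcast(g / o.data, self.data.shape)),
            (o, lambda g: _unbroadcast(-g * self.data / (o.data ** 2), o.data.shape)),
        ])

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        out = self.data ** p
        return Tensor._make(out, [(self, lambda g: g * p * self.data ** (p - 1))])

    def __getitem__(self, idx):
        out = self.data[idx]

        def back(g, idx=idx):
            full = np.zeros_like(self.data)
            full[idx] = g
            return full

        return Tensor._make(out, [(self, back)])

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return np.broadcast_to(g, self.data.shape).copy()

        return Tensor._make(out, [(self, back)])

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = self.data.reshape(shape)
        return Tensor._make(out, [(self, lambda g: g.reshape(self.data.shape))])

    def transpose(self, axes):
        inv = np.argsort(axes)
        out = self.data.transpose(axes)
        return Tensor._make(out, [(self, lambda g: g.transpose(inv))])

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self):
        out = np.maximum(self.data, 0.0)
        mask = self.data > 0

        return Tensor._make(out, [(self, lambda g: g * mask)])

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(out, [(self, lambda g: g * out * (1.0 - out))])

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor._make(out, [(self, lambda g: g * (1.0 - out ** 2))])

    def exp(self):
        out = np.exp(self.data)
        return Tensor._make(out, [(self, lambda g: g * out)])

    def log(self):
        return Tensor._make(np.log(self.data), [(self, lambda g: g / self.data)])

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor._make(out, [(self, lambda g: g * 0.5 / out)])

    def abs(self):
        sign = np.sign(self.data)
        return Tensor._make(np.abs(self.data), [(self, lambda g: g * sign)])

    def softmax(self, axis: int = 1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out = e / e.sum(axis=axis, keepdims=True)

        def back(g):
            return out * (g - (g * out).sum(axis=axis, keepdims=True))

        return Tensor._make(out, [(self, back)])


def concat(tensors, axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis`` (channel axis by default)."""
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    parents = []
    start = 0
    for t in tensors:
        size = t.data.shape[axis]
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(start, start + size)
        sl = tuple(sl)
        parents.append((t, lambda g, sl=sl: g[sl]))
        start += size
    return Tensor._make(out, parents)


def stack_sum(tensors) -> Tensor:
    """Sum a list of same-shaped tensors."""
    out = tensors[0]
    for t in tensors[1:]:
        out = out + t
    return out
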