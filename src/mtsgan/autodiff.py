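"""Minimal reverse-mode automatic differentiation over numpy arrays.

All recurrent networks in this package (the dual variational autoencoders,
the coupled bilateral-LSTM generator, the sequence discriminators and the
post-hoc critics) are trained with gradients produced by this tape-based
engine.  The design is deliberately small: a :class:`Tensor` wraps an
``ndarray``, records its parents and a backward closure, and ``backward()``
walks the tape in reverse topological order accumulating gradients.

Broadcasting is supported for elementwise binary ops; gradients are
un-broadcast by summing over the broadcast axes.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum axes that were broadcast from size 1
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph.

    Parameters
    ----------
    data:
        The wrapped array (coerced to float64).
    requires_grad:
        Whether gradients should be accumulated into ``.grad``.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[Array] = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Optional[Callable[[Array], Sequence[Optional[Array]]]] = None

    # -- graph construction -------------------------------------------------
    @staticmethod
    def _make(data: Array, parents: tuple["Tensor", ...],
              backward: Callable[[Array], Sequence[Optional[Array]]]) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        return Tensor._make(
            self.data + other.data, (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)))

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other) -> "Tensor":
        other = as_tensor(other)
        return Tensor._make(
            self.data - other.data, (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(-g, other.shape)))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) - self

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        return Tensor._make(
            self.data * other.data, (self, other),
            lambda g: (_unbroadcast(g * other.data, self.shape),
                       _unbroadcast(g * self.data, other.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        return Tensor._make(
            self.data / other.data, (self, other),
            lambda g: (_unbroadcast(g / other.data, self.shape),
                       _unbroadcast(-g * self.data / other.data ** 2, other.shape)))

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def __pow__(self, p: float) -> "Tensor":
        assert isinstance(p, (int, float))
        return Tensor._make(
            self.data ** p, (self,),
            lambda g: (g * p * self.data ** (p - 1),))

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)

        def bwd(g: Array):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)

        return Tensor._make(self.data @ other.data, (self, other), bwd)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        orig = self.shape
        return Tensor._make(self.data.reshape(*shape), (self,),
                            lambda g: (g.reshape(orig),))

    def transpose(self, *axes) -> "Tensor":
        inv = np.argsort(axes)
        return Tensor._make(self.data.transpose(*axes), (self,),
                            lambda g: (g.transpose(*inv),))

    def __getitem__(self, idx) -> "Tensor":
        def bwd(g: Array):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return (out,)
        return Tensor._make(self.data[idx], (self,), bwd)

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def bwd(g: Array):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)
        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities -----------------------------------------------------
    def exp(self) -> "Tensor":
        out = np.exp(self.data)
        return Tensor._make(out, (self,), lambda g: (g * out,))

    def log(self) -> "Tensor":
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self) -> "Tensor":
        out = np.sqrt(self.data)
        return Tensor._make(out, (self,), lambda g: (g * 0.5 / out,))

    def sigmoid(self) -> "Tensor":
        out = _sigmoid(self.data)
        return Tensor._make(out, (self,), lambda g: (g * out * (1.0 - out),))

    def tanh(self) -> "Tensor":
        out = np.tanh(self.data)
        return Tensor._make(out, (self,), lambda g: (g * (1.0 - out ** 2),))

    def softplus(self) -> "Tensor":
        """log(1+exp(x)), computed stably; derivative is sigmoid(x)."""
        out = np.logaddexp(0.0, self.data)
        return Tensor._make(out, (self,), lambda g: (g * _sigmoid(self.data),))

    # -- autodiff driver ----------------------------------------------------
    def backward(self, grad: Optional[Array] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs unroll over T timesteps
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

        grads: dict[int, Array] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                if node.grad is None:
                    node.grad = g.copy()
                else:
                    node.grad = node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


def _sigmoid(x: Array) -> Array:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g: Array):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tuple(tensors), bwd)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def bwd(g: Array):
        return tuple(np.take(g, i, axis=axis) for i in range(len(tensors)))

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis),
                        tuple(tensors), bwd)


def logsumexp(x: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    """Stable log-sum-exp with gradient softmax(x)."""
    m = np.max(x.data, axis=axis, keepdims=True)
    out = m + np.log(np.sum(np.exp(x.data - m), axis=axis, keepdims=True))
    soft = np.exp(x.data - out)
    res = out if keepdims else np.squeeze(out, axis=axis)

    def bwd(g: Array):
        gg = g if keepdims else np.expand_dims(g, axis)
        return (gg * soft,)

    return Tensor._make(res, (x,), bwd)


def check_grad(fn: Callable[..., Tensor], *args: Tensor, eps: float = 1e-6,
               rtol: float = 1e-4, atol: float = 1e-6) -> None:
    """Finite-difference check of ``fn``'s gradient w.r.t. every arg.

    Test utility: raises ``AssertionError`` on mismatch.
    """
    for a in args:
        a.grad = None
    out = fn(*args)
    out.backward()
    for a in args:
        num = np.zeros_like(a.data)
        flat = a.data.reshape(-1)
        numf = num.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            up = fn(*args).data.sum()
            flat[i] = orig - eps
            dn = fn(*args).data.sum()
            flat[i] = orig
            numf[i] = (up - dn) / (2 * eps)
        assert a.grad is not None, "no gradient reached argument"
        np.testing.assert_allclose(a.grad, num, rtol=rtol, atol=atol)
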