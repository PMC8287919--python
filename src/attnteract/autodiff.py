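"""Minimal reverse-mode automatic differentiation on numpy arrays.

The model layer needs gradients twice over: once with respect to the
parameters (training) and once with respect to the one-hot input
(Integrated Gradients attributions).  A small tape-based engine keeps
both paths in plain numpy.  Only the operations the network actually
uses are implemented: broadcast arithmetic, matmul, the pointwise
nonlinearities, a stable softmax, valid 1-D convolution and
non-overlapping max-pooling.

Conventions
-----------
- ``Tensor`` wraps a float64 ndarray.  ``requires_grad`` marks leaves
  whose ``.grad`` is populated by ``backward()``.
- Each non-leaf node stores its parents and a function mapping the
  output gradient to one gradient per parent; ``backward()`` runs a
  topological sort, so shared sub-expressions (DAGs) are handled.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "concatenate", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_grad_fn")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        # maps d(output) -> tuple of d(parent), aligned with _parents
        self._grad_fn: Callable[[np.ndarray], tuple] | None = None

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _from_op(cls, data, parents: Sequence["Tensor"],
                 grad_fn: Callable[[np.ndarray], tuple]) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._grad_fn = grad_fn
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # ------------------------------------------------------------------ autograd
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        # iterative post-order DFS: LSTM tapes are deep enough to overflow
        # python recursion
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._grad_fn is not None:
                for parent, pg in zip(node._parents, node._grad_fn(g)):
                    if pg is None or not parent.requires_grad:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg
            elif node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other)
        return Tensor._from_op(
            self.data + other.data, (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)))

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = self._lift(other)
        return Tensor._from_op(
            self.data - other.data, (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(-g, other.shape)))

    def __rsub__(self, other):
        return self._lift(other) - self

    def __mul__(self, other):
        other = self._lift(other)
        return Tensor._from_op(
            self.data * other.data, (self, other),
            lambda g: (_unbroadcast(g * other.data, self.shape),
                       _unbroadcast(g * self.data, other.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return Tensor._from_op(
            self.data / other.data, (self, other),
            lambda g: (_unbroadcast(g / other.data, self.shape),
                       _unbroadcast(-g * self.data / other.data ** 2, other.shape)))

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)
        return Tensor._from_op(
            self.data ** e, (self,),
            lambda g: (g * e * self.data ** (e - 1.0),))

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self.data, other.data

        def grad_fn(g):
            if a.ndim == 1 or b.ndim == 1:
                raise NotImplementedError("matmul backward requires >=2-D operands")
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return Tensor._from_op(a @ b, (self, other), grad_fn)

    # ------------------------------------------------------------- shape ops
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor._from_op(self.data.reshape(shape), (self,),
                               lambda g: (g.reshape(old),))

    def swapaxes(self, ax1: int, ax2: int):
        return Tensor._from_op(np.swapaxes(self.data, ax1, ax2), (self,),
                               lambda g: (np.swapaxes(g, ax1, ax2),))

    @property
    def T(self):
        if self.ndim != 2:
            raise ValueError(".T defined for 2-D tensors only")
        return self.swapaxes(0, 1)

    def __getitem__(self, idx):
        def grad_fn(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor._from_op(self.data[idx], (self,), grad_fn)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        def grad_fn(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor._from_op(self.data.sum(axis=axis, keepdims=keepdims),
                               (self,), grad_fn)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else (
            np.prod([self.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # --------------------------------------------------------- nonlinearities
    def relu(self):
        mask = self.data > 0
        return Tensor._from_op(np.where(mask, self.data, 0.0), (self,),
                               lambda g: (g * mask,))

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._from_op(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._from_op(np.log(self.data), (self,),
                               lambda g: (g / self.data,))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._from_op(s, (self,), lambda g: (g * s * (1.0 - s),))

    def softplus(self):
        """log(1 + e^x), computed without overflow for large |x|."""
        x = self.data
        out = np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))
        s = 1.0 / (1.0 + np.exp(-x))
        return Tensor._from_op(out, (self,), lambda g: (g * s,))

    def tanh(self):
        t = np.tanh(self.data)
        return Tensor._from_op(t, (self,), lambda g: (g * (1.0 - t * t),))

    def softmax(self, axis: int = -1):
        """Row-stochastic softmax with max-subtraction for stability."""
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def grad_fn(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            return (s * (g - dot),)

        return Tensor._from_op(s, (self,), grad_fn)

    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out = z - lse
        s = np.exp(out)

        def grad_fn(g):
            return (g - s * g.sum(axis=axis, keepdims=True),)

        return Tensor._from_op(out, (self,), grad_fn)

    # ------------------------------------------------------ structured layers
    def conv1d(self, weights: "Tensor") -> "Tensor":
        """Valid (no padding) cross-correlation.

        ``self``: (N, C, L) input; ``weights``: (F, C, A) filter bank.
        Returns (N, F, L - A + 1).
        """
        weights = self._lift(weights)
        x, w = self.data, weights.data
        if x.ndim != 3 or w.ndim != 3:
            raise ValueError("conv1d expects (N, C, L) input and (F, C, A) filters")
        n, c, length = x.shape
        f, cw, a = w.shape
        if cw != c:
            raise ValueError(f"channel mismatch: input has {c}, filters have {cw}")
        if a > length:
            raise ValueError(f"filter length {a} exceeds sequence length {length}")
        lout = length - a + 1
        # im2col: (N, L', C*A) patches, filters flattened to (C*A, F)
        cols = np.lib.stride_tricks.sliding_window_view(x, a, axis=2)  # (N,C,L',A)
        cols = cols.transpose(0, 2, 1, 3).reshape(n, lout, c * a)
        wmat = w.reshape(f, c * a).T
        out = (cols @ wmat).transpose(0, 2, 1)  # (N, F, L')

        def grad_fn(g):
            gt = g.transpose(0, 2, 1)                      # (N, L', F)
            gw = None
            gx = None
            if weights.requires_grad:
                gw = np.einsum("nlf,nlk->fk", gt, cols).reshape(f, c, a)
            if self.requires_grad:
                gcols = gt @ wmat.T                        # (N, L', C*A)
                gcols = gcols.reshape(n, lout, c, a)
                gx = np.zeros_like(x)
                for off in range(a):                       # a is small (filter length)
                    gx[:, :, off:off + lout] += gcols[:, :, :, off].transpose(0, 2, 1)
            return gx, gw

        return Tensor._from_op(out, (self, weights), grad_fn)

    def max_pool1d(self, window: int) -> "Tensor":
        """Non-overlapping max pooling along the last axis.

        Trailing positions that do not fill a window are dropped, so the
        output length is ``floor(L / window)``.
        """
        if window < 1:
            raise ValueError("pooling window must be >= 1")
        *lead, length = self.shape
        d = length // window
        trimmed = self.data[..., : d * window].reshape(*lead, d, window)
        idx = trimmed.argmax(axis=-1)
        out = np.take_along_axis(trimmed, idx[..., None], axis=-1)[..., 0]

        def grad_fn(g):
            gx = np.zeros((*lead, d, window), dtype=np.float64)
            np.put_along_axis(gx, idx[..., None], g[..., None], axis=-1)
            full = np.zeros_like(self.data)
            full[..., : d * window] = gx.reshape(*lead, d * window)
            return (full,)

        return Tensor._from_op(out, (self,), grad_fn)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def grad_fn(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._from_op(np.concatenate([t.data for t in tensors], axis=axis),
                           tensors, grad_fn)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]

    def grad_fn(g):
        return tuple(np.moveaxis(g, axis, 0))

    return Tensor._from_op(np.stack([t.data for t in tensors], axis=axis),
                           tensors, grad_fn)
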