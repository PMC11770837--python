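"""Minimal reverse-mode automatic differentiation on numpy arrays, plus the
Adam optimizer.  Supports exactly the operations the encoder and heads need:
broadcasted arithmetic, matmul, tanh/exp/log, reductions, indexing/gather,
concatenation, and stable softmax/log-softmax composites.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "softmax", "log_softmax", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (the reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents: tuple["Tensor", ...] = parents
        self._backward: Callable[[np.ndarray], None] | None = backward

    # -- structural ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def bw(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return Tensor(-self.data, parents=(self,), backward=bw)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bw(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self**-1.0

    def __pow__(self, exponent: float):
        def bw(g, a=self, p=float(exponent)):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1.0))

        return Tensor(self.data ** float(exponent), parents=(self,), backward=bw)

    def __matmul__(self, other):
        other = self._lift(other)

        def bw(g, a=self, b=other):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.shape))

        return Tensor(self.data @ other.data, parents=(self, other), backward=bw)

    # -- elementwise ---------------------------------------------------------
    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g, a=self, o=out_data):
            if a.requires_grad:
                a._accum(g * (1.0 - o * o))

        return Tensor(out_data, parents=(self,), backward=bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g, a=self, o=out_data):
            if a.requires_grad:
                a._accum(g * o)

        return Tensor(out_data, parents=(self,), backward=bw)

    def log(self):
        def bw(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bw)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g, a=self, ax=axis, kd=keepdims):
            if not a.requires_grad:
                return
            g = np.asarray(g)
            if ax is not None and not kd:
                g = np.expand_dims(g, ax)
            a._accum(np.broadcast_to(g, a.shape).copy())

        return Tensor(out_data, parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape

        def bw(g, a=self, s=old):
            if a.requires_grad:
                a._accum(g.reshape(s))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bw)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def bw(g, a=self, i=tuple(inv)):
            if a.requires_grad:
                a._accum(g.transpose(i))

        return Tensor(self.data.transpose(axes), parents=(self,), backward=bw)

    def __getitem__(self, idx):
        def bw(g, a=self, i=idx):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, i, g)
                a._accum(full)

        return Tensor(self.data[idx], parents=(self,), backward=bw)

    def take_rows(self, indices: np.ndarray):
        """Gather rows (embedding lookup); grad scatter-adds."""
        idx = np.asarray(indices)

        def bw(g, a=self, i=idx):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, i, g)
                a._accum(full)

        return Tensor(self.data[idx], parents=(self,), backward=bw)

    # -- autodiff machinery --------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g, ts=tensors, off=offsets, ax=axis):
        for t, a, b in zip(ts, off[:-1], off[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[ax] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward=bw,
    )


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    c = Tensor(x.data.max(axis=axis, keepdims=True))
    shifted = x - c
    lse = shifted.exp().sum(axis=axis, keepdims=True).log()
    return shifted - lse


class Adam:
    """Adam with the standard bias correction."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 5e-5,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
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
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
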