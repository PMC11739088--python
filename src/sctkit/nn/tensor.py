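"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small engine: a :class:`Tensor` wraps an ndarray, records its
parents and a backward closure, and ``backward()`` walks the graph in reverse
topological order.  Only the operations the toolkit's networks and losses
need are implemented, each with a numpy-vectorised gradient.  Arrays keep
their float dtype (float32 for training speed, float64 in gradient checks).
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence, Tuple, Union

import numpy as np

__all__ = ["Tensor", "stack", "concat"]

ArrayLike = Union[np.ndarray, float, int, "Tensor"]


def _as_data(x) -> np.ndarray:
    arr = np.asarray(x)
    if arr.dtype not in (np.float32, np.float64):
        arr = arr.astype(np.float32)
    return arr


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum a gradient back down to the shape it was broadcast from."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_data(data)
        self.requires_grad = bool(requires_grad)
        self.grad: Optional[np.ndarray] = None
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: Tuple["Tensor", ...] = ()

    # -- graph construction -------------------------------------------------
    @staticmethod
    def _op(data: np.ndarray, parents: Sequence["Tensor"], backward: Callable) -> "Tensor":
        out = Tensor(data)
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: "Tensor") -> None:
            stack_ = [t]
            order = []
            while stack_:
                node = stack_.pop()
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                order.append(node)
                stack_.extend(node._parents)
            topo.extend(order)

        # iterative DFS gives a usable order when combined with grad
        # accumulation: we process nodes in reverse discovery order after a
        # proper topological sort below
        visit(self)
        # Kahn-style topological sort on the discovered subgraph
        indeg = {id(t): 0 for t in topo}
        nodes = {id(t): t for t in topo}
        for t in topo:
            for p in t._parents:
                if id(p) in indeg:
                    indeg[id(p)] += 1
        ready = [t for t in topo if indeg[id(t)] == 0]
        ordered = []
        while ready:
            t = ready.pop()
            ordered.append(t)
            for p in t._parents:
                if id(p) in indeg:
                    indeg[id(p)] -= 1
                    if indeg[id(p)] == 0:
                        ready.append(nodes[id(p)])

        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for t in ordered:
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- conveniences -------------------------------------------------------
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other: ArrayLike) -> "Tensor":
        o = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data + o.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if o.requires_grad:
                o._accumulate(_unbroadcast(g, o.data.shape))

        return Tensor._op(data, (self, o), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._op(-self.data, (self,), backward)

    def __sub__(self, other: ArrayLike) -> "Tensor":
        return self + (-other if isinstance(other, Tensor) else Tensor(-_as_data(other)))

    def __rsub__(self, other: ArrayLike) -> "Tensor":
        return (-self) + other

    def __mul__(self, other: ArrayLike) -> "Tensor":
        o = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data * o.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * o.data, self.data.shape))
            if o.requires_grad:
                o._accumulate(_unbroadcast(g * self.data, o.data.shape))

        return Tensor._op(data, (self, o), backward)

    __rmul__ = __mul__

    def __truediv__(self, other: ArrayLike) -> "Tensor":
        o = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data / o.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / o.data, self.data.shape))
            if o.requires_grad:
                o._accumulate(_unbroadcast(-g * self.data / (o.data**2), o.data.shape))

        return Tensor._op(data, (self, o), backward)

    def __rtruediv__(self, other: ArrayLike) -> "Tensor":
        return Tensor(other) / self

    def __pow__(self, p: float) -> "Tensor":
        data = self.data**p

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        return Tensor._op(data, (self,), backward)

    def __matmul__(self, other: "Tensor") -> "Tensor":
        o = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data @ o.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(o.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if o.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                o._accumulate(_unbroadcast(gb, o.data.shape))

        return Tensor._op(data, (self, o), backward)

    # -- elementwise nonlinearities ------------------------------------------
    def exp(self) -> "Tensor":
        data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * data)

        return Tensor._op(data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._op(np.log(self.data), (self,), backward)

    def sqrt(self) -> "Tensor":
        return self**0.5

    def tanh(self) -> "Tensor":
        data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - data**2))

        return Tensor._op(data, (self,), backward)

    def abs(self) -> "Tensor":
        sign = np.sign(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * sign)

        return Tensor._op(np.abs(self.data), (self,), backward)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._op(self.data * mask, (self,), backward)

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        factor = np.where(self.data > 0, 1.0, slope).astype(self.data.dtype)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * factor)

        return Tensor._op(self.data * factor, (self,), backward)

    def clamp_min(self, lo: float) -> "Tensor":
        mask = self.data > lo

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._op(np.maximum(self.data, lo), (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if self.requires_grad:
                gg = np.asarray(g)
                if axis is not None and not keepdims:
                    gg = np.expand_dims(gg, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._op(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        data = self.data.max(axis=axis, keepdims=True)
        mask = self.data == data
        counts = mask.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                gg = np.asarray(g)
                if not keepdims:
                    gg = np.expand_dims(gg, axis)
                self._accumulate(gg * mask / counts)

        out = data if keepdims else data.squeeze(axis=axis)
        return Tensor._op(out, (self,), backward)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src_shape = self.data.shape
        data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(src_shape))

        return Tensor._op(data, (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return Tensor._op(self.data.transpose(axes), (self,), backward)

    def broadcast_to(self, shape: Tuple[int, ...]) -> "Tensor":
        src = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, src))

        return Tensor._op(np.broadcast_to(self.data, shape).copy(), (self,), backward)

    def __getitem__(self, idx) -> "Tensor":
        data = self.data[idx]

        fancy = any(
            isinstance(i, (np.ndarray, list)) for i in (idx if isinstance(idx, tuple) else (idx,))
        )

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                if fancy:
                    np.add.at(full, idx, g)
                else:
                    full[idx] += g
                self._accumulate(full)

        return Tensor._op(data, (self,), backward)

    def roll(self, shift, axis) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accumulate(np.roll(g, tuple(-s for s in np.atleast_1d(shift)), axis))

        return Tensor._op(np.roll(self.data, shift, axis), (self,), backward)

    def pad_edge2d(self, pad_y: int, pad_x: int) -> "Tensor":
        """Replicate-pad the last two axes; gradient accumulates back onto
        the clipped source indices."""
        h, w = self.data.shape[-2:]
        iy = np.clip(np.arange(-pad_y, h + pad_y), 0, h - 1)
        ix = np.clip(np.arange(-pad_x, w + pad_x), 0, w - 1)
        data = self.data[..., iy[:, None], ix[None, :]]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                lead = full.reshape(-1, h, w)
                gl = g.reshape(-1, g.shape[-2], g.shape[-1])
                for b in range(lead.shape[0]):
                    np.add.at(lead[b], (iy[:, None], ix[None, :]), gl[b])
                self._accumulate(lead.reshape(self.data.shape))

        return Tensor._op(data, (self,), backward)

    def pad_zero2d(self, pad_y: int, pad_x: int) -> "Tensor":
        widths = [(0, 0)] * (self.data.ndim - 2) + [(pad_y, pad_y), (pad_x, pad_x)]
        data = np.pad(self.data, widths)
        sl = (Ellipsis, slice(pad_y, pad_y + self.data.shape[-2]), slice(pad_x, pad_x + self.data.shape[-1]))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g[sl])

        return Tensor._op(data, (self,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    return Tensor._op(data, tensors, backward)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    shaped = []
    for t in tensors:
        shape = list(t.data.shape)
        shape.insert(axis if axis >= 0 else t.data.ndim + 1 + axis, 1)
        shaped.append(t.reshape(tuple(shape)))
    return concat(shaped, axis=axis)
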