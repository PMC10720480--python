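"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough tensor calculus to train the affinity network on a CPU:
broadcast arithmetic, (batched) matmul, the activations, reductions,
shape ops, gather/scatter primitives for graph message passing and
convolution patch extraction, and segment reductions for variable-size
graph pooling.  float64 throughout; gradients accumulate into ``.grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # -- infrastructure -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if id(node) in seen:
                continue
            if expanded:
                seen.add(id(node))
                topo.append(node)
                continue
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -----------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        req = self.requires_grad or other.requires_grad
        out = Tensor(self.data + other.data, req, (self, other))

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def back(g):
            if self.requires_grad:
                self._accum(-g)

        out._backward = back
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        req = self.requires_grad or other.requires_grad
        out = Tensor(self.data * other.data, req, (self, other))

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, self.requires_grad, (self,))

        def back(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1.0))

        out._backward = back
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        req = self.requires_grad or other.requires_grad
        out = Tensor(self.data @ other.data, req, (self, other))

        def back(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = back
        return out

    # -- activations / elementwise -------------------------------------

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))

        def back(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        out._backward = back
        return out

    def leaky_relu(self, negative_slope: float = 0.2):
        slope = np.where(self.data > 0, 1.0, negative_slope)
        out = Tensor(self.data * slope, self.requires_grad, (self,))

        def back(g):
            if self.requires_grad:
                self._accum(g * slope)

        out._backward = back
        return out

    def exp(self):
        value = np.exp(self.data)
        out = Tensor(value, self.requires_grad, (self,))

        def back(g):
            if self.requires_grad:
                self._accum(g * value)

        out._backward = back
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def back(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = back
        return out

    def sqrt(self):
        return self ** 0.5

    # -- reductions -----------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def back(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max_last(self):
        """Maximum over the last axis; gradient flows to the argmax."""
        arg = np.argmax(self.data, axis=-1)
        value = np.take_along_axis(self.data, arg[..., None], axis=-1)[..., 0]
        out = Tensor(value, self.requires_grad, (self,))

        def back(g):
            if self.requires_grad:
                gx = np.zeros_like(self.data)
                np.put_along_axis(gx, arg[..., None], g[..., None], axis=-1)
                self._accum(gx)

        out._backward = back
        return out

    # -- shape ops ------------------------------------------------------

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def back(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = back
        return out

    def transpose(self, axes):
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        inverse = np.argsort(axes)

        def back(g):
            if self.requires_grad:
                self._accum(g.transpose(inverse))

        out._backward = back
        return out

    def pad_last(self, pad_widths: tuple[tuple[int, int], ...]):
        """Zero-pad the trailing axes (leading axes untouched)."""
        lead = self.ndim - len(pad_widths)
        spec = [(0, 0)] * lead + list(pad_widths)
        out = Tensor(np.pad(self.data, spec), self.requires_grad, (self,))
        slicer = tuple(
            slice(lo, lo + size) for (lo, _), size in zip(spec, self.data.shape)
        )

        def back(g):
            if self.requires_grad:
                self._accum(g[slicer])

        out._backward = back
        return out

    # -- gather / scatter ----------------------------------------------

    def take_last(self, idx: np.ndarray):
        """Gather along the last axis with an integer index array.

        ``y[..., *idx.shape] = x[..., idx]``; the backward pass scatter-adds.
        """
        idx = np.asarray(idx, dtype=np.int64)
        out = Tensor(self.data[..., idx], self.requires_grad, (self, ))

        def back(g):
            if not self.requires_grad:
                return
            lead = int(np.prod(self.data.shape[:-1], dtype=np.int64)) or 1
            # build the scatter target flat and C-ordered, then reshape:
            # zeros_like on a strided view could make reshape return a copy
            # and the scatter-add would be lost
            gxv = np.zeros((lead, self.data.shape[-1]))
            gv = np.ascontiguousarray(g).reshape(lead, idx.size)
            np.add.at(gxv, (np.arange(lead)[:, None], idx.ravel()[None, :]), gv)
            self._accum(gxv.reshape(self.data.shape))

        out._backward = back
        return out

    def rows(self, idx: np.ndarray):
        """Gather rows (first axis): ``y = x[idx]``; backward scatter-adds."""
        idx = np.asarray(idx, dtype=np.int64)
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def back(g):
            if self.requires_grad:
                gx = np.zeros_like(self.data)
                np.add.at(gx, idx, g)
                self._accum(gx)

        out._backward = back
        return out

    def segment_sum(self, segment_ids: np.ndarray, num_segments: int):
        """Sum rows into ``num_segments`` buckets given per-row segment ids."""
        segment_ids = np.asarray(segment_ids, dtype=np.int64)
        value = np.zeros((num_segments,) + self.data.shape[1:])
        np.add.at(value, segment_ids, self.data)
        out = Tensor(value, self.requires_grad, (self,))

        def back(g):
            if self.requires_grad:
                self._accum(g[segment_ids])

        out._backward = back
        return out

    def segment_max(self, segment_ids: np.ndarray, num_segments: int):
        """Per-segment, per-feature maximum; gradient routes to the argmax row."""
        segment_ids = np.asarray(segment_ids, dtype=np.int64)
        n_feat = self.data.shape[1]
        value = np.full((num_segments, n_feat), -np.inf)
        np.maximum.at(value, segment_ids, self.data)
        # first row achieving the max in each segment/feature
        argrow = np.full((num_segments, n_feat), self.data.shape[0], dtype=np.int64)
        hit_rows, hit_cols = np.nonzero(value[segment_ids] == self.data)
        np.minimum.at(argrow, (segment_ids[hit_rows], hit_cols), hit_rows)
        argrow = np.minimum(argrow, self.data.shape[0] - 1)  # guard empty segments
        out = Tensor(value, self.requires_grad, (self,))

        def back(g):
            if self.requires_grad:
                gx = np.zeros_like(self.data)
                cols = np.broadcast_to(np.arange(n_feat), argrow.shape)
                np.add.at(gx, (argrow.ravel(), cols.ravel()), g.ravel())
                self._accum(gx)

        out._backward = back
        return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    req = any(t.requires_grad for t in tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), req, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                slicer = [slice(None)] * g.ndim
                slicer[axis] = slice(lo, hi)
                t._accum(g[tuple(slicer)])

    out._backward = back
    return out
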