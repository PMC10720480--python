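"""Neural layers on top of the autograd engine.

Conventions: parameters are float64 ``Tensor``s with ``requires_grad=True``;
initialization is Glorot-uniform from a caller-supplied
``numpy.random.Generator`` so a single integer seed fixes the whole model.
Convolutions use "same" zero padding and are implemented as patch gather
(im2col) followed by one matmul; max pooling has window 2, stride 2, and
drops trailing odd rows/columns.
"""

from __future__ import annotations

import itertools

import numpy as np

from .autograd import Tensor

__all__ = [
    "Module", "Linear", "Conv2d", "Conv3d", "MaxPool", "BatchNorm1d",
    "Dropout", "Sequential", "Adam", "glorot",
]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Base class with parameter discovery and train/eval mode switching."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def train(self, mode: bool = True):
        self.training = mode
        for value in vars(self).values():
            if isinstance(value, Module):
                value.train(mode)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_arrays(self) -> list[np.ndarray]:
        """All parameter arrays plus buffers, for checkpointing."""
        arrays = [p.data for p in self.parameters()]
        arrays.extend(self._buffers())
        return arrays

    def _buffers(self) -> list[np.ndarray]:
        buffers: list[np.ndarray] = []
        for value in vars(self).values():
            if isinstance(value, Module):
                buffers.extend(value._buffers())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        buffers.extend(item._buffers())
        return buffers

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state: list[np.ndarray]) -> None:
        arrays = self.state_arrays()
        if len(arrays) != len(state):
            raise ValueError("checkpoint does not match model structure")
        for target, source in zip(arrays, state):
            target[...] = source


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(glorot(rng, in_features, out_features,
                                    (in_features, out_features)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.weight.shape[0]:
            raise ValueError(
                f"shape mismatch: input has {x.shape[-1]} features, "
                f"weight expects {self.weight.shape[0]}")
        return x @ self.weight + self.bias


class _ConvNd(Module):
    """Same-padding convolution as one fused autograd node.

    Forward gathers im2col patches with a cached index matrix and contracts
    them against the weight with ``tensordot``.  The input gradient is the
    transposed convolution, realized as *another gather* (each padded
    position is covered by at most K windows) instead of a scatter-add —
    ``np.ufunc.at`` is far too slow for the inner training loop.
    """

    ndim_spatial: int

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator,
                 kernel_size: int = 3):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        k_elems = kernel_size ** self.ndim_spatial
        fan_in = in_channels * k_elems
        self.weight = Tensor(glorot(rng, fan_in, out_channels, (fan_in, out_channels)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self._index_cache: dict[tuple[int, ...], tuple[np.ndarray, np.ndarray]] = {}

    def _indices(self, spatial: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
        """Forward gather (P, K) and adjoint gather (S_pad, K) index maps."""
        if spatial in self._index_cache:
            return self._index_cache[spatial]
        pad = self.kernel_size // 2
        padded = tuple(s + 2 * pad for s in spatial)
        strides = np.cumprod((1,) + padded[::-1][:-1])[::-1]
        offsets = np.array([
            sum(o * st for o, st in zip(off, strides))
            for off in itertools.product(range(self.kernel_size), repeat=self.ndim_spatial)
        ], dtype=np.int64)
        starts = np.array([
            sum(p * st for p, st in zip(pos, strides))
            for pos in itertools.product(*(range(s) for s in spatial))
        ], dtype=np.int64)
        idx = starts[:, None] + offsets[None, :]                    # (P, K)
        n_pad, n_out, n_k = int(np.prod(padded)), idx.shape[0], idx.shape[1]
        # adjoint map: window covering padded position s via kernel slot k
        idx_t = np.full((n_pad, n_k), n_out, dtype=np.int64)        # sentinel = n_out
        for k in range(n_k):
            idx_t[idx[:, k], k] = np.arange(n_out)
        self._index_cache[spatial] = (idx, idx_t)
        return idx, idx_t

    def __call__(self, x: Tensor) -> Tensor:
        batch, channels = x.shape[0], x.shape[1]
        spatial = tuple(x.shape[2:])
        if channels != self.in_channels or len(spatial) != self.ndim_spatial:
            raise ValueError(
                f"expected (B, {self.in_channels}, {'x'.join('S' * self.ndim_spatial)}) "
                f"input, got shape {x.shape}")
        pad = self.kernel_size // 2
        idx, idx_t = self._indices(spatial)
        n_k = idx.shape[1]
        spec = [(0, 0), (0, 0)] + [(pad, pad)] * self.ndim_spatial
        xpad = np.pad(x.data, spec).reshape(batch, channels, -1)
        cols = xpad[:, :, idx]                                       # (B, C, P, K)
        w3 = self.weight.data.reshape(channels, n_k, self.out_channels)
        value = np.tensordot(cols, w3, axes=([1, 3], [0, 1]))        # (B, P, Cout)
        value = value + self.bias.data
        out_shape = (batch, self.out_channels) + spatial
        out = Tensor(np.moveaxis(value, -1, 1).reshape(out_shape),
                     x.requires_grad or self.weight.requires_grad,
                     (x, self.weight, self.bias))
        conv = self

        def back(g):
            gflat = np.moveaxis(g.reshape(batch, conv.out_channels, -1), 1, -1)  # (B,P,Co)
            if conv.bias.requires_grad:
                conv.bias._accum(gflat.sum(axis=(0, 1)))
            if conv.weight.requires_grad:
                gw3 = np.tensordot(cols, gflat, axes=([0, 2], [0, 1]))  # (C, K, Co)
                conv.weight._accum(gw3.reshape(conv.weight.data.shape))
            if x.requires_grad:
                gcols = np.tensordot(gflat, w3, axes=([2], [2]))        # (B, P, C, K)
                gcols = np.ascontiguousarray(np.moveaxis(gcols, 2, 1))  # (B, C, P, K)
                guard = np.zeros((batch, channels, 1, n_k))
                gcols = np.concatenate([gcols, guard], axis=2)          # sentinel row
                gathered = gcols[:, :, idx_t, np.arange(n_k)]           # (B, C, S_pad, K)
                gxpad = gathered.sum(axis=-1)
                padded = tuple(s + 2 * pad for s in spatial)
                gxpad = gxpad.reshape((batch, channels) + padded)
                slicer = (slice(None), slice(None)) + tuple(
                    slice(pad, pad + s) for s in spatial)
                x._accum(gxpad[slicer])

        out._backward = back
        return out


class Conv2d(_ConvNd):
    ndim_spatial = 2


class Conv3d(_ConvNd):
    ndim_spatial = 3


class MaxPool(Module):
    """Non-overlapping window-2 max pooling over all spatial axes (floor)."""

    def __init__(self, ndim_spatial: int):
        super().__init__()
        self.ndim_spatial = ndim_spatial

    def _window_indices(self, spatial: tuple[int, ...]) -> np.ndarray:
        """(P_out, 2**d) flat indices of each pooling window (cached)."""
        key = spatial
        cache = getattr(self, "_cache", None)
        if cache is None:
            cache = self._cache = {}
        if key in cache:
            return cache[key]
        out_spatial = tuple(s // 2 for s in spatial)
        strides = np.cumprod((1,) + spatial[::-1][:-1])[::-1]
        starts = np.array([
            sum(2 * p * st for p, st in zip(pos, strides))
            for pos in itertools.product(*(range(o) for o in out_spatial))
        ], dtype=np.int64)
        offsets = np.array([
            sum(o * st for o, st in zip(off, strides))
            for off in itertools.product(range(2), repeat=self.ndim_spatial)
        ], dtype=np.int64)
        idx = starts[:, None] + offsets[None, :]
        cache[key] = idx
        return idx

    def __call__(self, x: Tensor) -> Tensor:
        batch, channels = x.shape[0], x.shape[1]
        spatial = tuple(x.shape[2:])
        out_spatial = tuple(s // 2 for s in spatial)
        idx = self._window_indices(spatial)
        flat = np.ascontiguousarray(x.data).reshape(batch, channels, -1)
        windows = flat[:, :, idx]                       # (B, C, P, 2**d)
        arg = np.argmax(windows, axis=-1)
        value = np.take_along_axis(windows, arg[..., None], axis=-1)[..., 0]
        out = Tensor(value.reshape((batch, channels) + out_spatial),
                     x.requires_grad, (x,))
        if x.requires_grad:
            argflat = idx[np.arange(idx.shape[0]), arg]  # (B, C, P) winner positions

            def back(g):
                gx = np.zeros((batch, channels, flat.shape[-1]))
                # windows are disjoint, so each input cell wins at most once
                np.put_along_axis(
                    gx, argflat.reshape(batch, channels, -1),
                    g.reshape(batch, channels, -1), axis=-1)
                x._accum(gx.reshape(x.data.shape))

            out._backward = back
        return out


class BatchNorm1d(Module):
    """Batch normalization over the row axis of (N, features) tensors."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def _buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=0, keepdims=True)
            self.running_mean[...] = ((1 - self.momentum) * self.running_mean
                                      + self.momentum * mu.data[0])
            self.running_var[...] = ((1 - self.momentum) * self.running_var
                                     + self.momentum * var.data[0])
            xhat = centered * (var + self.eps) ** -0.5
        else:
            xhat = (x - self.running_mean) * (self.running_var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity in eval mode or at rate 0."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * mask


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.modules = list(modules)

    def __call__(self, x: Tensor) -> Tensor:
        for module in self.modules:
            x = module(x)
        return x


class Adam:
    """Adam optimizer over a parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * p.grad
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * p.grad ** 2
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
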