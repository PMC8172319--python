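"""Building blocks for the 3D convolutional network.

All layers operate on float32 arrays in ``(N, C, D, H, W)`` layout (batch,
channel, three spatial axes) except :class:`Dense` and the 1-D flavour of
:class:`BatchNorm`, which use ``(N, F)``.  Every layer implements

* ``forward(x, training)`` — returns the output and caches whatever the
  backward pass needs;
* ``backward(grad_out, need_param_grads)`` — accumulates parameter gradients
  (unless disabled) and returns the gradient with respect to the input.

Convolutions use kernel 3x3x3, stride 1 and zero padding of one voxel
("same" shape); pooling uses window 3x3x3, stride 2 and one-voxel padding so
each pooling halves every spatial dimension (ceil division).  The inner
loops of convolution and pooling are numba-compiled (:mod:`._kernels`),
which is what makes CPU training practical.
"""

from __future__ import annotations

import numpy as np

from . import _kernels

__all__ = [
    "Parameter",
    "Layer",
    "BatchNorm",
    "Conv3D",
    "ReLU",
    "MaxPool3D",
    "Flatten",
    "Dropout",
    "Dense",
    "Sigmoid",
]


class Parameter:
    """A trainable array with an accumulated gradient.

    ``regularized`` marks kernels that receive the L2 penalty (conv and dense
    weights; biases and batch-norm scales are exempt).
    """

    __slots__ = ("value", "grad", "regularized", "name")

    def __init__(self, value: np.ndarray, regularized: bool = False, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.regularized = regularized
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray, need_param_grads: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    # layers with state beyond params (batch-norm running moments) override these
    def extra_state(self) -> dict:
        return {}

    def load_extra_state(self, state: dict) -> None:
        pass


class BatchNorm(Layer):
    """Batch normalization over the batch (and spatial axes for 5-D input).

    In training mode the batch moments are used and the running moments are
    updated with exponential momentum; in inference mode the running moments
    are used, so the layer is a fixed per-channel affine map (which keeps
    single-example forward/backward passes, e.g. for saliency, well defined).
    """

    def __init__(self, n_channels: int, momentum: float = 0.9, eps: float = 1e-5, name: str = "bn"):
        self.gamma = Parameter(np.ones(n_channels), name=f"{name}.gamma")
        self.beta = Parameter(np.zeros(n_channels), name=f"{name}.beta")
        self.momentum = float(momentum)
        self.eps = float(eps)
        self.running_mean = np.zeros(n_channels, dtype=np.float32)
        self.running_var = np.ones(n_channels, dtype=np.float32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def extra_state(self):
        return {"running_mean": self.running_mean.copy(), "running_var": self.running_var.copy()}

    def load_extra_state(self, state):
        self.running_mean = state["running_mean"].copy()
        self.running_var = state["running_var"].copy()

    def _axes_and_shape(self, x):
        if x.ndim == 2:
            return (0,), (1, -1)
        if x.ndim == 5:
            return (0, 2, 3, 4), (1, -1, 1, 1, 1)
        raise ValueError(f"BatchNorm expects 2-D or 5-D input, got {x.ndim}-D")

    def forward(self, x, training):
        axes, bshape = self._axes_and_shape(x)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(np.float32)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(bshape)) * inv_std.reshape(bshape)
        xhat = xhat.astype(np.float32, copy=False)
        self._cache = (xhat, inv_std.astype(np.float32), axes, bshape, training)
        return self.gamma.value.reshape(bshape) * xhat + self.beta.value.reshape(bshape)

    def backward(self, grad_out, need_param_grads=True):
        xhat, inv_std, axes, bshape, training = self._cache
        g = self.gamma.value.reshape(bshape)
        if need_param_grads:
            self.gamma.grad += (grad_out * xhat).sum(axis=axes)
            self.beta.grad += grad_out.sum(axis=axes)
        if not training:
            return grad_out * g * inv_std.reshape(bshape)
        m = xhat.size // xhat.shape[1] if xhat.ndim == 5 else xhat.shape[0]
        dxhat = grad_out * g
        # standard batch-norm backward: couples every example through the batch moments
        term = dxhat - dxhat.mean(axis=axes).reshape(bshape) \
            - xhat * (dxhat * xhat).mean(axis=axes).reshape(bshape)
        return (term * inv_std.reshape(bshape)).astype(np.float32, copy=False)


class Conv3D(Layer):
    """3x3x3 convolution, stride 1, zero padding 1, He-initialised kernels.

    The kernel tensor is stored as ``(C_in, 3, 3, 3, C_out)``.  Forward,
    input-gradient and kernel-gradient passes run through the numba loops in
    :mod:`vbmnet.nn._kernels`; the input gradient reuses the forward kernel
    on the padded output gradient with spatially flipped, channel-transposed
    weights (the standard "full correlation" identity).
    """

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator, name: str = "conv"):
        fan_in = in_channels * 27
        std = np.sqrt(2.0 / fan_in)
        self.w = Parameter(rng.normal(0.0, std, size=(in_channels, 3, 3, 3, out_channels)),
                           regularized=True, name=f"{name}.w")
        self.b = Parameter(np.zeros(out_channels), name=f"{name}.b")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training):
        xp = _zero_pad1(np.asarray(x, dtype=np.float32))
        out = _kernels.conv3d_fwd(xp, self.w.value, self.b.value)
        self._cache = xp if training else None
        return out

    def backward(self, grad_out, need_param_grads=True):
        g = np.ascontiguousarray(grad_out, dtype=np.float32)
        if need_param_grads:
            xp = self._cache
            if xp is None:
                raise RuntimeError("Conv3D parameter gradients need a training-mode forward pass")
            self.w.grad += _kernels.conv3d_wgrad(xp, g)
            self.b.grad += g.sum(axis=(0, 2, 3, 4))
        w_t = np.ascontiguousarray(
            self.w.value[:, ::-1, ::-1, ::-1, :].transpose(4, 1, 2, 3, 0))
        return _kernels.conv3d_fwd(_zero_pad1(g), w_t,
                                   np.zeros(self.in_channels, dtype=np.float32))


def _zero_pad1(x: np.ndarray) -> np.ndarray:
    """Zero padding of 1 on the three spatial axes (faster than np.pad)."""
    n, c, d, h, w = x.shape
    xp = np.zeros((n, c, d + 2, h + 2, w + 2), dtype=np.float32)
    xp[:, :, 1:-1, 1:-1, 1:-1] = x
    return xp


class ReLU(Layer):
    def forward(self, x, training):
        out = np.maximum(x, np.float32(0.0))
        self._mask = out > 0
        return out

    def backward(self, grad_out, need_param_grads=True):
        grad_out = np.asarray(grad_out)
        grad_out[~self._mask] = 0.0  # grads are layer-owned buffers; in-place is safe
        return grad_out


class MaxPool3D(Layer):
    """Max pooling with window 3, stride 2, padding 1 (output = ceil(dim/2))."""

    def forward(self, x, training):
        x = np.ascontiguousarray(x, dtype=np.float32)
        out, idx = _kernels.maxpool3d_fwd(x)
        self._cache = (idx, x.shape)
        return out

    def backward(self, grad_out, need_param_grads=True):
        idx, (n, c, d, h, w) = self._cache
        g = np.ascontiguousarray(grad_out, dtype=np.float32)
        return _kernels.maxpool3d_bwd(idx, g, d, h, w)


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out, need_param_grads=True):
        return grad_out.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity in inference mode.

    The sampling generator is injected per forward call (via ``set_rng``) so
    the training loop controls reproducibility.
    """

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = float(rate)
        self._rng = np.random.default_rng(0)
        self._mask = None

    def set_rng(self, rng: np.random.Generator) -> None:
        self._rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self._rng.random(x.shape) < keep).astype(np.float32) / np.float32(keep)
        return x * self._mask

    def backward(self, grad_out, need_param_grads=True):
        if self._mask is None:
            return grad_out
        return grad_out * self._mask


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, name: str = "dense"):
        std = np.sqrt(2.0 / in_features)
        self.w = Parameter(rng.normal(0.0, std, size=(in_features, out_features)),
                           regularized=True, name=f"{name}.w")
        self.b = Parameter(np.zeros(out_features), name=f"{name}.b")
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training):
        self._cache = x if training else None
        self._last_x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad_out, need_param_grads=True):
        if need_param_grads:
            x = self._cache if self._cache is not None else self._last_x
            self.w.grad += x.T @ grad_out
            self.b.grad += grad_out.sum(axis=0)
        return grad_out @ self.w.value.T


class Sigmoid(Layer):
    def forward(self, x, training):
        # numerically stable two-branch logistic
        out = np.empty_like(x, dtype=np.float32)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._out = out
        return out

    def backward(self, grad_out, need_param_grads=True):
        return grad_out * self._out * (1.0 - self._out)
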