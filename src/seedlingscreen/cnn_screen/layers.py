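"""Minimal CPU neural-network layers with explicit backprop.

Only what the residual classifiers need: bias-free 2-D convolution
(im2col), batch normalisation, ReLU, max/global-average pooling and a
fully connected head. Every layer caches what its backward pass needs;
``Module`` provides recursive parameter/buffer traversal, train/eval mode
switching and (de)serialisation of the state as flat arrays.

All arithmetic is float32; initialisation draws from a caller-supplied
``numpy.random.Generator`` so a whole network is reproducible from one
seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

__all__ = [
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
    "count_parameters",
    "conv_output_size",
]


def conv_output_size(size: int, kernel: int, stride: int, padding: int) -> int:
    """Spatial output size of a convolution/pooling window."""
    return (size + 2 * padding - kernel) // stride + 1


class Module:
    """Base class: leaf layers store arrays in ``params``/``grads``/``buffers``."""

    def __init__(self) -> None:
        self.training = True
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}

    # -- structure -----------------------------------------------------
    def children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, "Module", str]]:
        for key in self.params:
            yield prefix + key, self, key
        for cname, child in self.children():
            yield from child.named_parameters(prefix + cname + ".")

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, "Module", str]]:
        for key in self.buffers:
            yield prefix + key, self, key
        for cname, child in self.children():
            yield from child.named_buffers(prefix + cname + ".")

    # -- mode / gradients ---------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, child in self.children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for _, module, key in self.named_parameters():
            module.grads[key] = np.zeros_like(module.params[key])

    # -- state ---------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: module.params[key].copy() for name, module, key in self.named_parameters()}
        for name, module, key in self.named_buffers():
            state[name] = module.buffers[key].copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, module, key in self.named_parameters():
            module.params[key] = np.array(state[name], dtype=np.float32)
        for name, module, key in self.named_buffers():
            module.buffers[key] = np.array(state[name], dtype=np.float32)

    # -- interface -----------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def count_parameters(module: Module) -> int:
    """Number of trainable parameters (buffers excluded)."""
    return sum(m.params[k].size for _, m, k in module.named_parameters())


# ---------------------------------------------------------------------
# im2col helpers


def _im2col(x: np.ndarray, k: int, stride: int, pad: int, pad_value: float = 0.0):
    n, c, h, w = x.shape
    oh = conv_output_size(h, k, stride, pad)
    ow = conv_output_size(w, k, stride, pad)
    if pad:
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=pad_value)
    else:
        xp = x
    cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols, oh, ow, xp.shape


def _col2im(dcols: np.ndarray, xp_shape, k: int, stride: int, pad: int, oh: int, ow: int):
    dxp = np.zeros(xp_shape, dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += dcols[:, :, i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


# ---------------------------------------------------------------------


class Conv2d(Module):
    """Bias-free 2-D convolution (batch norm supplies the shift)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)  # He initialisation for ReLU networks
        self.params["weight"] = rng.normal(
            0.0, std, size=(out_channels, in_channels, kernel_size, kernel_size)
        ).astype(np.float32)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, oh, ow, xp_shape = _im2col(x, self.kernel_size, self.stride, self.padding)
        n = x.shape[0]
        cols2 = cols.reshape(n, -1, oh * ow)
        wmat = self.params["weight"].reshape(self.out_channels, -1)
        y = np.matmul(wmat, cols2)
        if self.training:
            self._cache = (cols2, xp_shape, oh, ow)
        return y.reshape(n, self.out_channels, oh, ow)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols2, xp_shape, oh, ow = self._cache
        n = grad.shape[0]
        gflat = grad.reshape(n, self.out_channels, oh * ow)
        dw = np.tensordot(gflat, cols2, axes=([0, 2], [0, 2]))
        self.grads["weight"] = dw.reshape(self.params["weight"].shape)
        wmat = self.params["weight"].reshape(self.out_channels, -1)
        dcols = np.matmul(wmat.T, gflat)
        dcols = dcols.reshape(n, self.in_channels, self.kernel_size, self.kernel_size, oh, ow)
        return _col2im(dcols, xp_shape, self.kernel_size, self.stride, self.padding, oh, ow)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params["weight"] = np.ones(num_features, dtype=np.float32)
        self.params["bias"] = np.zeros(num_features, dtype=np.float32)
        self.buffers["running_mean"] = np.zeros(num_features, dtype=np.float32)
        self.buffers["running_var"] = np.ones(num_features, dtype=np.float32)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = x.shape[0] * x.shape[2] * x.shape[3]
            unbiased = var * m / max(m - 1, 1)
            self.buffers["running_mean"] = (
                (1 - self.momentum) * self.buffers["running_mean"] + self.momentum * mean
            ).astype(np.float32)
            self.buffers["running_var"] = (
                (1 - self.momentum) * self.buffers["running_var"] + self.momentum * unbiased
            ).astype(np.float32)
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        y = self.params["weight"][None, :, None, None] * xhat + self.params["bias"][None, :, None, None]
        self._cache = (xhat, invstd)
        return y.astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, invstd = self._cache
        self.grads["weight"] = (grad * xhat).sum(axis=(0, 2, 3)).astype(np.float32)
        self.grads["bias"] = grad.sum(axis=(0, 2, 3)).astype(np.float32)
        dxhat = grad * self.params["weight"][None, :, None, None]
        if not self.training:
            return (dxhat * invstd[None, :, None, None]).astype(np.float32)
        mean_dxhat = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        dx = invstd[None, :, None, None] * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)
        return dx.astype(np.float32)


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0).astype(np.float32)


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int, padding: int = 0) -> None:
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, oh, ow, xp_shape = _im2col(
            x, self.kernel_size, self.stride, self.padding, pad_value=-np.inf
        )
        n, c = x.shape[:2]
        kk = self.kernel_size * self.kernel_size
        cols = cols.reshape(n, c, kk, oh * ow)
        argmax = cols.argmax(axis=2)
        y = np.take_along_axis(cols, argmax[:, :, None, :], axis=2)[:, :, 0, :]
        self._cache = (argmax, xp_shape, oh, ow, (n, c, kk))
        return y.reshape(n, c, oh, ow).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        argmax, xp_shape, oh, ow, (n, c, kk) = self._cache
        dcols = np.zeros((n, c, kk, oh * ow), dtype=grad.dtype)
        np.put_along_axis(dcols, argmax[:, :, None, :], grad.reshape(n, c, 1, oh * ow), axis=2)
        dcols = dcols.reshape(n, c, self.kernel_size, self.kernel_size, oh, ow)
        return _col2im(dcols, xp_shape, self.kernel_size, self.stride, self.padding, oh, ow)


class GlobalAvgPool(Module):
    """Average over the spatial grid; output (N, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3)).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return (np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)).astype(np.float32)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = 1.0 / np.sqrt(in_features)
        self.params["weight"] = rng.uniform(-bound, bound, size=(out_features, in_features)).astype(
            np.float32
        )
        self.params["bias"] = rng.uniform(-bound, bound, size=out_features).astype(np.float32)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        return (x @ self.params["weight"].T + self.params["bias"]).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._cache
        self.grads["weight"] = (grad.T @ x).astype(np.float32)
        self.grads["bias"] = grad.sum(axis=0).astype(np.float32)
        return (grad @ self.params["weight"]).astype(np.float32)


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad
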