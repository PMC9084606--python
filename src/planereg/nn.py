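"""Minimal 3D convolutional network layers with manual backpropagation.

A compact, dependency-free layer stack sized for small volumetric pose
regressors: 3D convolution (odd kernel, zero 'same' padding), ReLU, batch
normalization, 2x max pooling (ceil mode), adaptive max pooling, linear
layers, mean-squared-error loss, and SGD with classical momentum.  All
computation is float32 numpy; convolutions are evaluated as one matmul per
kernel offset, which keeps memory low and is fast at the problem sizes used
here.  Every layer caches what its backward pass needs; ``zero_grad`` resets
accumulated gradients.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Module",
    "Conv3d",
    "ReLU",
    "BatchNorm3d",
    "MaxPool3d",
    "AdaptiveMaxPool3d",
    "Flatten",
    "Linear",
    "Sequential",
    "mse_loss",
    "SGD",
    "he_normal",
]

_DT = np.float32


class Parameter:
    """A trainable array with its gradient accumulator."""

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=_DT)
        self.grad = np.zeros_like(self.data)


def he_normal(shape, fan_in: int, rng: np.random.Generator) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(_DT)


class Module:
    training: bool = True

    def parameters(self):
        out = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
            elif isinstance(v, dict):
                for item in v.values():
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def train(self, mode: bool = True):
        self.training = mode
        for v in vars(self).values():
            if isinstance(v, Module):
                v.train(mode)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train(mode)
            elif isinstance(v, dict):
                for item in v.values():
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def __call__(self, x):
        return self.forward(x)


class Conv3d(Module):
    """3D convolution, odd kernel, stride 1, zero 'same' padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * kernel**3
        self.weight = Parameter(he_normal((c_out, c_in, kernel, kernel, kernel), fan_in, rng))
        self.bias = Parameter(np.zeros(c_out))

    def forward(self, x):
        k, p = self.kernel, self.kernel // 2
        B, C, D, H, W = x.shape
        x = np.ascontiguousarray(x, dtype=_DT)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        self._xp_shape = xp.shape
        self._xp = xp
        N = D * H * W
        out = np.zeros((B, self.c_out, N), dtype=_DT)
        Wk = self.weight.data
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    xs = xp[:, :, i : i + D, j : j + H, l : l + W].reshape(B, C, N)
                    out += Wk[:, :, i, j, l] @ xs
        out += self.bias.data[None, :, None]
        self._out_spatial = (D, H, W)
        return out.reshape(B, self.c_out, D, H, W)

    def backward(self, dout):
        k = self.kernel
        B, _, D, H, W = dout.shape
        N = D * H * W
        df = dout.reshape(B, self.c_out, N).astype(_DT)
        xp = self._xp
        dxp = np.zeros(self._xp_shape, dtype=_DT)
        Wk = self.weight.data
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    xs = xp[:, :, i : i + D, j : j + H, l : l + W].reshape(B, self.c_in, N)
                    self.weight.grad[:, :, i, j, l] += np.einsum(
                        "bon,bin->oi", df, xs, optimize=True
                    )
                    dxs = (Wk[:, :, i, j, l].T @ df).reshape(B, self.c_in, D, H, W)
                    dxp[:, :, i : i + D, j : j + H, l : l + W] += dxs
        self.bias.grad += df.sum(axis=(0, 2))
        p = k // 2
        self._xp = None
        return dxp[:, :, p : p + D, p : p + H, p : p + W]


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class BatchNorm3d(Module):
    """Per-channel batch normalization over (batch, spatial) axes."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels, dtype=_DT)
        self.running_var = np.ones(channels, dtype=_DT)

    def forward(self, x):
        axes = (0, 2, 3, 4)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(_DT)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(_DT)
        else:
            mean, var = self.running_mean, self.running_var
        shape = (1, -1, 1, 1, 1)
        self._inv_std = (1.0 / np.sqrt(var + self.eps)).reshape(shape).astype(_DT)
        self._xhat = ((x - mean.reshape(shape)) * self._inv_std).astype(_DT)
        return self.gamma.data.reshape(shape) * self._xhat + self.beta.data.reshape(shape)

    def backward(self, dout):
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        xhat, inv_std = self._xhat, self._inv_std
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        if not self.training:
            return dout * self.gamma.data.reshape(shape) * inv_std
        n = dout.shape[0] * dout.shape[2] * dout.shape[3] * dout.shape[4]
        dxhat = dout * self.gamma.data.reshape(shape)
        term = (
            dxhat
            - dxhat.mean(axis=axes).reshape(shape)
            - xhat * (dxhat * xhat).mean(axis=axes).reshape(shape)
        )
        return (term * inv_std).astype(_DT)


class MaxPool3d(Module):
    """2x2x2 max pooling with ceil mode (odd sizes padded with -inf)."""

    def forward(self, x):
        B, C, D, H, W = x.shape
        Do, Ho, Wo = -(-D // 2), -(-H // 2), -(-W // 2)
        pad = ((0, 0), (0, 0), (0, 2 * Do - D), (0, 2 * Ho - H), (0, 2 * Wo - W))
        xp = np.pad(x, pad, constant_values=-np.inf)
        xr = xp.reshape(B, C, Do, 2, Ho, 2, Wo, 2)
        xr = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(B, C, Do, Ho, Wo, 8)
        self._idx = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        B, C, D, H, W = self._in_shape
        Do, Ho, Wo = dout.shape[2:]
        dxr = np.zeros((B, C, Do, Ho, Wo, 8), dtype=_DT)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        dxp = (
            dxr.reshape(B, C, Do, Ho, Wo, 2, 2, 2)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(B, C, 2 * Do, 2 * Ho, 2 * Wo)
        )
        return dxp[:, :, :D, :H, :W]


class AdaptiveMaxPool3d(Module):
    """Max pooling onto a fixed output grid with torch-style window bounds."""

    def __init__(self, out_size):
        self.out_size = tuple(out_size)

    @staticmethod
    def _bounds(n_in, n_out):
        return [
            (int(np.floor(i * n_in / n_out)), int(np.ceil((i + 1) * n_in / n_out)))
            for i in range(n_out)
        ]

    def forward(self, x):
        B, C, D, H, W = x.shape
        Do, Ho, Wo = self.out_size
        out = np.empty((B, C, Do, Ho, Wo), dtype=_DT)
        self._argmax = np.empty((B, C, Do, Ho, Wo, 3), dtype=np.int64)
        bd = self._bounds(D, Do)
        bh = self._bounds(H, Ho)
        bw = self._bounds(W, Wo)
        for a, (d0, d1) in enumerate(bd):
            for b, (h0, h1) in enumerate(bh):
                for c, (w0, w1) in enumerate(bw):
                    win = x[:, :, d0:d1, h0:h1, w0:w1].reshape(B, C, -1)
                    flat = win.argmax(axis=-1)
                    out[:, :, a, b, c] = np.take_along_axis(
                        win, flat[..., None], axis=-1
                    )[..., 0]
                    nd, nh, nw = d1 - d0, h1 - h0, w1 - w0
                    self._argmax[:, :, a, b, c, 0] = d0 + flat // (nh * nw)
                    self._argmax[:, :, a, b, c, 1] = h0 + (flat // nw) % nh
                    self._argmax[:, :, a, b, c, 2] = w0 + flat % nw
        self._in_shape = x.shape
        return out

    def backward(self, dout):
        dx = np.zeros(self._in_shape, dtype=_DT)
        B, C, Do, Ho, Wo = dout.shape
        bi, ci = np.meshgrid(np.arange(B), np.arange(C), indexing="ij")
        for a in range(Do):
            for b in range(Ho):
                for c in range(Wo):
                    am = self._argmax[:, :, a, b, c]
                    np.add.at(
                        dx,
                        (bi, ci, am[..., 0], am[..., 1], am[..., 2]),
                        dout[:, :, a, b, c],
                    )
        return dx


class Flatten(Module):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = Parameter(he_normal((n_out, n_in), n_in, rng))
        self.bias = Parameter(np.zeros(n_out))

    def forward(self, x):
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dout):
        self.weight.grad += dout.T @ self._x
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.data


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error over every output node; returns (loss, grad)."""
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    diff = (pred - target).astype(_DT)
    loss = float(np.mean(diff**2))
    return loss, (2.0 / diff.size) * diff


class SGD:
    """Minibatch gradient descent with classical momentum and step decay."""

    def __init__(self, params, lr: float, momentum: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._velocity):
            v *= self.momentum
            v += p.grad
            p.data -= (self.lr * v).astype(p.data.dtype)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0
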