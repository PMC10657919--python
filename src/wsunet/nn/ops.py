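"""Differentiable array operations used by the network architectures.

Convolutions are implemented as im2col + BLAS matmul, which is the fastest
portable strategy in pure numpy.  Layout is channels-last (NHWC), matching
the (height, width, channels) shape convention of the model configs.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = [
    "conv2d",
    "conv_transpose2x2",
    "max_pool2x2",
    "global_max_pool2d",
    "batch_norm",
    "spatial_dropout",
    "relu",
    "sigmoid",
    "dense",
    "flatten",
    "concat_channels",
    "sigmoid_bce_with_logits",
]


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """'same'-padded patch matrix: (N*H*W, kh*kw*Cin), stride 1, odd kernels."""
    ph, pw = kh // 2, kw // 2
    if ph or pw:
        x = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    # (N, H, W, Cin, kh, kw) -> (N, H, W, kh, kw, Cin)
    cols = sliding_window_view(x, (kh, kw), axis=(1, 2))
    cols = np.ascontiguousarray(cols.transpose(0, 1, 2, 4, 5, 3))
    n, h, w = cols.shape[:3]
    return cols.reshape(n * h * w, kh * kw * x.shape[3])


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """2D convolution, stride 1, 'same' padding, odd square kernel.

    Forward is im2col + one matmul; the patch matrix is kept for the weight
    gradient.  The input gradient scatters ``gy @ w[a,b].T`` back into a
    padded buffer per kernel offset, avoiding a second im2col.
    """
    kh, kw, cin, cout = w.shape
    n, h, wd = x.shape[0], x.shape[1], x.shape[2]
    ph, pw = kh // 2, kw // 2
    cols = _im2col(x.data, kh, kw)
    y = (cols @ w.data.reshape(kh * kw * cin, cout) + b.data).reshape(n, h, wd, cout)

    def vjp(gy: np.ndarray):
        nonlocal cols
        gym = gy.reshape(-1, cout)
        gw = (cols.T @ gym).reshape(kh, kw, cin, cout)
        cols = None  # free the patch matrix as soon as the weight grad is done
        gb = gym.sum(axis=0)
        # dx is the 'same' correlation of gy with the spatially flipped,
        # channel-transposed kernel (valid because kernels are odd).
        w_adj = np.ascontiguousarray(w.data[::-1, ::-1].transpose(0, 1, 3, 2))
        gcols = _im2col(gy, kh, kw)
        gx = (gcols @ w_adj.reshape(kh * kw * cout, cin)).reshape(n, h, wd, cin)
        return gx, gw, gb

    return Tensor(y, (x, w, b), vjp)


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Transposed convolution, 2x2 kernel, stride 2 (non-overlapping upsampling).

    ``w`` has shape (2, 2, Cin, Cout); output spatial dims double.
    """
    n, h, wd, cin = x.shape
    _, _, _, cout = w.shape
    wm = w.data.transpose(2, 0, 1, 3).reshape(cin, 4 * cout)
    y = x.data.reshape(n * h * wd, cin) @ wm
    y = y.reshape(n, h, wd, 2, 2, cout).transpose(0, 1, 3, 2, 4, 5)
    y = y.reshape(n, 2 * h, 2 * wd, cout) + b.data

    def vjp(gy: np.ndarray):
        gyr = gy.reshape(n, h, 2, wd, 2, cout).transpose(0, 1, 3, 2, 4, 5)
        gym = gyr.reshape(n * h * wd, 4 * cout)
        xm = x.data.reshape(n * h * wd, cin)
        gw = (xm.T @ gym).reshape(cin, 2, 2, cout).transpose(1, 2, 0, 3)
        gb = gy.sum(axis=(0, 1, 2))
        gx = (gym @ wm.T).reshape(n, h, wd, cin)
        return gx, gw, gb

    return Tensor(y, (x, w, b), vjp)


def max_pool2x2(x: Tensor) -> Tensor:
    n, h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    xr = x.data.reshape(n, h2, 2, w2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, h2, w2, 4, c)
    idx = xr.argmax(axis=3)
    y = np.take_along_axis(xr, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def vjp(gy: np.ndarray):
        gxr = np.zeros_like(xr)
        np.put_along_axis(gxr, idx[:, :, :, None, :], gy[:, :, :, None, :], axis=3)
        gx = gxr.reshape(n, h2, w2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, h, w, c)
        return (gx,)

    return Tensor(y, (x,), vjp)


def global_max_pool2d(x: Tensor) -> Tensor:
    """Reduce (N, H, W, C) to (N, C) by the spatial maximum."""
    n, h, w, c = x.shape
    flat = x.data.reshape(n, h * w, c)
    idx = flat.argmax(axis=1)
    y = np.take_along_axis(flat, idx[:, None, :], axis=1)[:, 0, :]

    def vjp(gy: np.ndarray):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, idx[:, None, :], gy[:, None, :], axis=1)
        return (gflat.reshape(n, h, w, c),)

    return Tensor(y, (x,), vjp)


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.99,
    eps: float = 1e-3,
) -> Tensor:
    """Per-channel batch normalisation over the (N, H, W) axes.

    In training mode batch statistics are used and the running statistics
    (plain arrays, not graph nodes) are updated in place.
    """
    axes = tuple(range(x.data.ndim - 1))
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= momentum
        running_mean += (1.0 - momentum) * mean
        running_var *= momentum
        running_var += (1.0 - momentum) * var
    else:
        mean = running_mean
        var = running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * inv_std
    y = gamma.data * xhat + beta.data

    if training:

        def vjp(gy: np.ndarray):
            m = np.prod([x.data.shape[a] for a in axes])
            gbeta = gy.sum(axis=axes)
            ggamma = (gy * xhat).sum(axis=axes)
            gx = (gamma.data * inv_std) * (
                gy - gbeta / m - xhat * (ggamma / m)
            )
            return gx.astype(x.dtype, copy=False), ggamma, gbeta

    else:

        def vjp(gy: np.ndarray):
            gbeta = gy.sum(axis=axes)
            ggamma = (gy * xhat).sum(axis=axes)
            gx = gy * (gamma.data * inv_std)
            return gx.astype(x.dtype, copy=False), ggamma, gbeta

    return Tensor(y.astype(x.dtype, copy=False), (x, gamma, beta), vjp)


def spatial_dropout(x: Tensor, rate: float, training: bool, rng: Optional[np.random.Generator]) -> Tensor:
    """Channel-wise dropout: whole feature maps are zeroed with probability ``rate``."""
    if not training or rate <= 0.0:
        return x
    n, _, _, c = x.shape
    keep = (rng.random((n, 1, 1, c)) >= rate).astype(x.dtype)
    scale = np.asarray(1.0 / (1.0 - rate), dtype=x.dtype)
    mask = keep * scale
    y = x.data * mask

    def vjp(gy: np.ndarray):
        return (gy * mask,)

    return Tensor(y, (x,), vjp)


def relu(x: Tensor) -> Tensor:
    y = np.maximum(x.data, 0)

    def vjp(gy: np.ndarray):
        return (gy * (x.data > 0),)

    return Tensor(y, (x,), vjp)


def sigmoid(x: Tensor) -> Tensor:
    y = _sigmoid_stable(x.data)

    def vjp(gy: np.ndarray):
        return (gy * y * (1.0 - y),)

    return Tensor(y, (x,), vjp)


def _sigmoid_stable(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def dense(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Fully connected layer on (N, F) inputs."""
    y = x.data @ w.data + b.data

    def vjp(gy: np.ndarray):
        return gy @ w.data.T, x.data.T @ gy, gy.sum(axis=0)

    return Tensor(y, (x, w, b), vjp)


def flatten(x: Tensor) -> Tensor:
    n = x.shape[0]
    shape = x.shape
    y = x.data.reshape(n, -1)

    def vjp(gy: np.ndarray):
        return (gy.reshape(shape),)

    return Tensor(y, (x,), vjp)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.shape[-1]
    y = np.concatenate([a.data, b.data], axis=-1)

    def vjp(gy: np.ndarray):
        return gy[..., :ca], gy[..., ca:]

    return Tensor(y, (a, b), vjp)


def sigmoid_bce_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean binary cross-entropy between ``sigmoid(logits)`` and labels.

    Computed in the numerically stable logit form; returns a scalar tensor.
    """
    z = logits.data
    y = np.asarray(labels, dtype=z.dtype)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    value = np.asarray(loss.mean(), dtype=z.dtype)

    def vjp(gl: np.ndarray):
        g = (_sigmoid_stable(z) - y) / z.size
        return (gl * g,)

    return Tensor(value, (logits,), vjp)
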