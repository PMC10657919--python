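"""Layer objects: stateful wrappers around the functional ops.

Each layer knows its kind (used to build the model's layer catalogue),
exposes its trainable parameters, and remembers the output tensor of the
most recent forward pass so that attribution methods can read activations
and gradients at any depth.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

from . import ops
from .tensor import Parameter, Tensor

__all__ = [
    "Layer",
    "Conv2D",
    "ConvTranspose2D",
    "BatchNorm",
    "SpatialDropout",
    "MaxPool2D",
    "Dense",
    "Flatten",
    "GlobalMaxPool2D",
    "glorot_uniform",
]


def glorot_uniform(rng: np.random.Generator, shape: Tuple[int, ...], fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    kind: str = "layer"

    def __init__(self) -> None:
        self.last_output: Optional[Tensor] = None
        self.output_shape: Optional[Tuple[int, ...]] = None  # per-sample, set by builder

    def params(self) -> List[Parameter]:
        return []

    def _record(self, out: Tensor) -> Tensor:
        self.last_output = out
        return out


class Conv2D(Layer):
    kind = "conv"

    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        k = kernel
        fan_in, fan_out = k * k * cin, k * k * cout
        self.w = Parameter(glorot_uniform(rng, (k, k, cin, cout), fan_in, fan_out, dtype))
        self.b = Parameter(np.zeros(cout, dtype=dtype))

    def params(self):
        return [self.w, self.b]

    def __call__(self, x: Tensor, training: bool = False, rng=None) -> Tensor:
        return self._record(ops.conv2d(x, self.w, self.b))


class ConvTranspose2D(Layer):
    kind = "conv_transpose"

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        fan_in, fan_out = 4 * cin, 4 * cout
        self.w = Parameter(glorot_uniform(rng, (2, 2, cin, cout), fan_in, fan_out, dtype))
        self.b = Parameter(np.zeros(cout, dtype=dtype))

    def params(self):
        return [self.w, self.b]

    def __call__(self, x: Tensor, training: bool = False, rng=None) -> Tensor:
        return self._record(ops.conv_transpose2x2(x, self.w, self.b))


class BatchNorm(Layer):
    kind = "batch_norm"

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3, dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor, training: bool = False, rng=None) -> Tensor:
        return self._record(
            ops.batch_norm(
                x, self.gamma, self.beta, self.running_mean, self.running_var,
                training, self.momentum, self.eps,
            )
        )


class SpatialDropout(Layer):
    kind = "dropout"

    def __init__(self, rate: float):
        super().__init__()
        self.rate = rate

    def __call__(self, x: Tensor, training: bool = False, rng=None) -> Tensor:
        return self._record(ops.spatial_dropout(x, self.rate, training, rng))


class MaxPool2D(Layer):
    kind = "max_pool"

    def __call__(self, x: Tensor, training: bool = False, rng=None) -> Tensor:
        return self._record(ops.max_pool2x2(x))


class Dense(Layer):
    kind = "dense"

    def __init__(self, nin: int, nout: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.w = Parameter(glorot_uniform(rng, (nin, nout), nin, nout, dtype))
        self.b = Parameter(np.zeros(nout, dtype=dtype))

    def params(self):
        return [self.w, self.b]

    def __call__(self, x: Tensor, training: bool = False, rng=None) -> Tensor:
        return self._record(ops.dense(x, self.w, self.b))


class Flatten(Layer):
    kind = "flatten"

    def __call__(self, x: Tensor, training: bool = False, rng=None) -> Tensor:
        return self._record(ops.flatten(x))


class GlobalMaxPool2D(Layer):
    kind = "global_max_pool"

    def __call__(self, x: Tensor, training: bool = False, rng=None) -> Tensor:
        return self._record(ops.global_max_pool2d(x))


class Activation(Layer):
    kind = "activation"

    def __init__(self, name: str):
        super().__init__()
        if name not in ("relu", "sigmoid"):
            raise ValueError(f"unsupported activation: {name}")
        self.name = name

    def __call__(self, x: Tensor, training: bool = False, rng=None) -> Tensor:
        fn = ops.relu if self.name == "relu" else ops.sigmoid
        return self._record(fn(x))
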