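"""WSUnet and standard-CNN architectures behind a common model handle.

The weakly supervised U-Net (WSUnet) is a plain U-Net producing a
full-resolution voxel-probability map, topped with a global max-pooling
head: the image-level probability *is* the maximal voxel probability.
Training therefore needs only image-level labels, while the voxel map is a
causally faithful explanation of the image decision.

The comparator ("standard" CNN, sCNN) shares the U-Net contracting path
including the 128-channel bottleneck and classifies through a
flatten -> dense(128, relu) -> dense(1, sigmoid) head; it has no voxel
output and must be explained post hoc (see :mod:`wsunet.saliency`).

Reference configurations: depth 4 with base width 8 doubling to a
128-channel bottleneck, two 3x3 convolutions with batch normalisation per
block, 2x2 transposed-convolution upsampling and a 1x1 sigmoid output.
At 128x128x1 input this yields 487,145 trainable parameters for WSUnet and
1,344,729 for the sCNN (487 k / 1344 k truncated to thousands), and the
sCNN's 7th and 9th convolutional layers produce (16,16,64) and (8,8,128)
feature grids — the layers used for Grad-CAM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError
from .nn import layers as L
from .nn.tensor import Parameter, Tensor, backward, no_grad

__all__ = [
    "WSUnetConfig",
    "SCNNConfig",
    "LayerInfo",
    "ModelHandle",
    "build_wsunet",
    "build_scnn",
    "global_max_pool",
    "count_trainable_parameters",
    "load_model",
]


@dataclass(frozen=True)
class WSUnetConfig:
    """Architecture of the weakly supervised U-Net.

    ``depth`` counts down/up-sampling levels; channel width starts at
    ``base_filters`` and doubles per level, so the bottleneck carries
    ``base_filters * 2**depth`` channels.
    """

    input_shape: Tuple[int, int, int] = (128, 128, 1)
    depth: int = 4
    base_filters: int = 8
    batch_norm: bool = True
    spatial_dropout_rate: float = 0.1
    # Voxel positives are rare, so the voxel-logit bias starts at a negative
    # prior: the initial max-pooled image probability then sits well below
    # saturation and positive images drive learning from the first step.
    output_bias_init: float = -2.0

    def __post_init__(self):
        h, w, _ = self.input_shape
        f = 2**self.depth
        if h % f or w % f:
            raise ConfigurationError(
                f"input spatial dims {h}x{w} must be divisible by 2**depth = {f}"
            )
        if self.base_filters < 1:
            raise ConfigurationError("base_filters must be >= 1")
        if not (0.0 <= self.spatial_dropout_rate < 1.0):
            raise ConfigurationError("spatial_dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class SCNNConfig:
    """Standard-CNN comparator: the WSUnet encoder plus a dense head."""

    input_shape: Tuple[int, int, int] = (128, 128, 1)
    depth: int = 4
    base_filters: int = 8
    batch_norm: bool = True
    spatial_dropout_rate: float = 0.1
    dense_width: int = 128

    def __post_init__(self):
        WSUnetConfig(self.input_shape, self.depth, self.base_filters,
                     self.batch_norm, self.spatial_dropout_rate)
        if self.dense_width < 1:
            raise ConfigurationError("dense_width must be >= 1")


@dataclass(frozen=True)
class LayerInfo:
    index: int
    kind: str
    output_shape: Tuple[int, ...]


class _Catalogue:
    """Collects layer objects in forward order with per-sample output shapes."""

    def __init__(self) -> None:
        self.layers: List[L.Layer] = []
        self.shapes: List[Tuple[int, ...]] = []

    def add(self, layer: L.Layer, shape: Tuple[int, ...]) -> L.Layer:
        layer.output_shape = shape
        self.layers.append(layer)
        self.shapes.append(shape)
        return layer

    def info(self) -> List[LayerInfo]:
        return [LayerInfo(i, l.kind, s) for i, (l, s) in enumerate(zip(self.layers, self.shapes))]


class ModelHandle:
    """A trained (or freshly initialised) classifier with introspection hooks.

    The handle exposes image-level prediction, the voxel-probability map
    (WSUnet only), per-layer activations and gradients, the trainable
    parameter count and an ordered layer catalogue — the contract the
    training and saliency modules rely on.  For the WSUnet,
    ``predict_image`` is computed as the maximum of ``predict_voxels`` on
    the same forward pass, so the two agree bitwise.
    """

    def __init__(
        self,
        name: str,
        config,
        catalogue: _Catalogue,
        forward_fn: Callable[[Tensor, bool, Optional[np.random.Generator]], Dict[str, Tensor]],
        has_voxel_output: bool,
        seed: int,
        dtype=np.float32,
    ):
        self.name = name
        self.config = config
        self._catalogue = catalogue
        self._forward_fn = forward_fn
        self.has_voxel_output = has_voxel_output
        self.seed = seed
        self.dtype = dtype

    # -- forward ---------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False,
                rng: Optional[np.random.Generator] = None) -> Dict[str, Tensor]:
        """Run one forward pass, returning the graph's named output tensors.

        ``x`` has shape (N, H, W, C).  Layer outputs stay attached to the
        layer objects for activation/gradient inspection.
        """
        xt = Tensor(np.asarray(x, dtype=self.dtype))
        return self._forward_fn(xt, training, rng)

    def _batched(self, x: np.ndarray, key: str, batch_size: int) -> np.ndarray:
        outs = []
        with no_grad():
            for i in range(0, len(x), batch_size):
                outs.append(self.forward(x[i:i + batch_size])[key].data)
        return np.concatenate(outs, axis=0)

    def predict_voxels(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Voxel-probability maps (N, H, W), inference mode (dropout off)."""
        if not self.has_voxel_output:
            raise NotImplementedError(f"{self.name} has no voxel-level output")
        return self._batched(np.asarray(x), "voxel_probs", batch_size)[..., 0]

    def predict_image(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Image-level probabilities (N,).

        For the WSUnet this is literally ``predict_voxels(x).max`` — the
        global max-pooling head.
        """
        if self.has_voxel_output:
            vox = self.predict_voxels(x, batch_size)
            return vox.reshape(len(vox), -1).max(axis=1)
        return self._batched(np.asarray(x), "image_prob", batch_size)[:, 0]

    # -- introspection ---------------------------------------------------
    @property
    def layer_catalogue(self) -> List[LayerInfo]:
        return self._catalogue.info()

    def conv_layer_index(self, n: int) -> int:
        """Catalogue index of the ``n``-th convolutional layer (1-based).

        Transposed convolutions count as convolutional layers, in forward
        order — the numbering convention behind "seventh/ninth
        convolutional layer".
        """
        seen = 0
        for info in self.layer_catalogue:
            if info.kind in ("conv", "conv_transpose"):
                seen += 1
                if seen == n:
                    return info.index
        raise IndexError(f"model has only {seen} convolutional layers")

    def layer(self, index: int) -> L.Layer:
        return self._catalogue.layers[index]

    def activations(self, layer_index: int, x: np.ndarray) -> np.ndarray:
        """Feature grid of a catalogue layer for a batch (inference mode)."""
        with no_grad():
            self.forward(np.asarray(x))
        out = self._catalogue.layers[layer_index].last_output
        return np.array(out.data)

    def gradients(self, x: np.ndarray, layer_index: Optional[int] = None) -> np.ndarray:
        """Gradient of the summed image-level probability wrt a layer or the input."""
        _, grad = self.activations_and_gradients(x, layer_index)
        return grad

    def activations_and_gradients(
        self, x: np.ndarray, layer_index: Optional[int] = None
    ) -> Tuple[np.ndarray, np.ndarray]:
        """One forward+backward pass: (activations, d sum(image_prob) / d activations).

        With ``layer_index=None`` the gradient is taken with respect to the
        input batch itself.
        """
        xt = Tensor(np.asarray(x, dtype=self.dtype), requires_grad=True)
        out = self._forward_fn(xt, False, None)
        backward(out["image_prob"])
        if layer_index is None:
            target = xt
        else:
            target = self._catalogue.layers[layer_index].last_output
        if target.grad is None:
            raise ValueError("no gradient reached the requested layer")
        return np.array(target.data), np.array(target.grad)

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        return self.gradients(x, layer_index=None)

    # -- parameters ------------------------------------------------------
    def parameters(self) -> List[Parameter]:
        out: List[Parameter] = []
        for layer in self._catalogue.layers:
            out.extend(layer.params())
        return out

    @property
    def trainable_parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def get_weights(self) -> List[np.ndarray]:
        """Trainable weights plus batch-norm running statistics, in order."""
        state: List[np.ndarray] = [p.data.copy() for p in self.parameters()]
        for layer in self._catalogue.layers:
            if isinstance(layer, L.BatchNorm):
                state.append(layer.running_mean.copy())
                state.append(layer.running_var.copy())
        return state

    def set_weights(self, state: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        for p, w in zip(params, state[: len(params)]):
            p.data = np.asarray(w, dtype=p.data.dtype).reshape(p.data.shape)
        rest = list(state[len(params):])
        for layer in self._catalogue.layers:
            if isinstance(layer, L.BatchNorm):
                layer.running_mean[...] = rest.pop(0)
                layer.running_var[...] = rest.pop(0)

    # -- persistence -----------------------------------------------------
    def architecture_summary(self) -> dict:
        return {
            "name": self.name,
            "config": asdict(self.config),
            "seed": self.seed,
            "trainable_parameters": self.trainable_parameter_count,
            "layers": [asdict(i) for i in self.layer_catalogue],
        }

    def save(self, path) -> None:
        """Write weights (npz) and a JSON architecture summary side by side."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path.with_suffix(".npz"),
                 *[np.asarray(w) for w in self.get_weights()])
        path.with_suffix(".json").write_text(
            json.dumps(self.architecture_summary(), indent=2))


def load_model(path) -> ModelHandle:
    """Rebuild a saved model from its JSON summary and npz weights."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = dict(meta["config"])
    cfg["input_shape"] = tuple(cfg["input_shape"])
    if meta["name"] == "wsunet":
        handle = build_wsunet(WSUnetConfig(**cfg), seed=meta["seed"])
    elif meta["name"] == "scnn":
        handle = build_scnn(SCNNConfig(**cfg), seed=meta["seed"])
    else:  # pragma: no cover - defensive
        raise ValueError(f"unknown architecture {meta['name']!r}")
    with np.load(path.with_suffix(".npz")) as npz:
        handle.set_weights([npz[k] for k in npz.files])
    return handle


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def _conv_block(cat: _Catalogue, cin: int, cout: int, shape: Tuple[int, int],
                cfg, rng, dtype) -> List[L.Layer]:
    """Two 3x3 convolutions, each followed by (optional) batch norm and relu,
    closed by one spatial-dropout layer."""
    h, w = shape
    seq: List[L.Layer] = []
    for c_in in (cin, cout):
        seq.append(cat.add(L.Conv2D(c_in, cout, 3, rng, dtype), (h, w, cout)))
        if cfg.batch_norm:
            seq.append(cat.add(L.BatchNorm(cout, dtype=dtype), (h, w, cout)))
        seq.append(cat.add(L.Activation("relu"), (h, w, cout)))
    if cfg.spatial_dropout_rate > 0:
        seq.append(cat.add(L.SpatialDropout(cfg.spatial_dropout_rate), (h, w, cout)))
    return seq


def _apply(seq: Sequence[L.Layer], x: Tensor, training: bool, rng) -> Tensor:
    for layer in seq:
        x = layer(x, training, rng)
    return x


def _build_encoder(cat: _Catalogue, cfg, rng, dtype):
    """Contracting path + bottleneck; returns (block seqs, pool layers, shapes)."""
    h, w, c = cfg.input_shape
    blocks, pools = [], []
    cin = c
    for level in range(cfg.depth):
        cout = cfg.base_filters * 2**level
        blocks.append(_conv_block(cat, cin, cout, (h, w), cfg, rng, dtype))
        pools.append(cat.add(L.MaxPool2D(), (h // 2, w // 2, cout)))
        h, w, cin = h // 2, w // 2, cout
    cbot = cfg.base_filters * 2**cfg.depth
    bottleneck = _conv_block(cat, cin, cbot, (h, w), cfg, rng, dtype)
    return blocks, pools, bottleneck, (h, w, cbot)


def build_wsunet(config: WSUnetConfig = WSUnetConfig(), seed: int = 0,
                 dtype=np.float32) -> ModelHandle:
    """Construct the weakly supervised U-Net with randomly initialised weights.

    Identical (config, seed) always yields identical weights and hence
    identical predictions.
    """
    rng = np.random.default_rng(seed)
    cat = _Catalogue()
    enc_blocks, pools, bottleneck, (h, w, cbot) = _build_encoder(cat, config, rng, dtype)

    upsamples, dec_blocks = [], []
    for level in reversed(range(config.depth)):
        cout = config.base_filters * 2**level
        cin = cout * 2
        h, w = h * 2, w * 2
        upsamples.append(cat.add(L.ConvTranspose2D(cin, cout, rng, dtype), (h, w, cout)))
        dec_blocks.append(_conv_block(cat, cout * 2, cout, (h, w), config, rng, dtype))

    hh, ww, _ = config.input_shape
    out_conv = cat.add(L.Conv2D(config.base_filters, 1, 1, rng, dtype), (hh, ww, 1))
    out_conv.b.data[:] = config.output_bias_init
    out_act = cat.add(L.Activation("sigmoid"), (hh, ww, 1))
    gmp = cat.add(L.GlobalMaxPool2D(), (1,))

    def forward_fn(x: Tensor, training: bool, frng) -> Dict[str, Tensor]:
        skips = []
        for blk, pool in zip(enc_blocks, pools):
            x = _apply(blk, x, training, frng)
            skips.append(x)
            x = pool(x, training, frng)
        x = _apply(bottleneck, x, training, frng)
        for up, blk, skip in zip(upsamples, dec_blocks, reversed(skips)):
            x = up(x, training, frng)
            from .nn.ops import concat_channels
            x = concat_channels(skip, x)
            x = _apply(blk, x, training, frng)
        voxel_logits = out_conv(x, training, frng)
        voxel_probs = out_act(voxel_logits, training, frng)
        image_logit = gmp(voxel_logits, training, frng)
        from .nn.ops import sigmoid as _sig
        image_prob = _sig(image_logit)
        return {
            "voxel_logits": voxel_logits,
            "voxel_probs": voxel_probs,
            "image_logit": image_logit,
            "image_prob": image_prob,
        }

    return ModelHandle("wsunet", config, cat, forward_fn, True, seed, dtype)


def build_scnn(config: SCNNConfig = SCNNConfig(), seed: int = 0,
               dtype=np.float32) -> ModelHandle:
    """Construct the standard-CNN comparator (encoder + dense head)."""
    rng = np.random.default_rng(seed)
    cat = _Catalogue()
    enc_blocks, pools, bottleneck, (h, w, cbot) = _build_encoder(cat, config, rng, dtype)

    nflat = h * w * cbot
    flat = cat.add(L.Flatten(), (nflat,))
    dense1 = cat.add(L.Dense(nflat, config.dense_width, rng, dtype), (config.dense_width,))
    act1 = cat.add(L.Activation("relu"), (config.dense_width,))
    dense2 = cat.add(L.Dense(config.dense_width, 1, rng, dtype), (1,))
    act2 = cat.add(L.Activation("sigmoid"), (1,))

    def forward_fn(x: Tensor, training: bool, frng) -> Dict[str, Tensor]:
        for blk, pool in zip(enc_blocks, pools):
            x = _apply(blk, x, training, frng)
            x = pool(x, training, frng)
        x = _apply(bottleneck, x, training, frng)
        x = flat(x, training, frng)
        x = act1(dense1(x, training, frng), training, frng)
        image_logit = dense2(x, training, frng)
        image_prob = act2(image_logit, training, frng)
        return {"image_logit": image_logit, "image_prob": image_prob}

    return ModelHandle("scnn", config, cat, forward_fn, False, seed, dtype)


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------


def global_max_pool(voxel_map: np.ndarray) -> float:
    """The image-level prediction of a voxel-probability map: its maximum."""
    voxel_map = np.asarray(voxel_map)
    if voxel_map.size == 0:
        raise ValueError("global max-pool of an empty grid is undefined")
    return float(voxel_map.max())


def count_trainable_parameters(handle: ModelHandle) -> int:
    """Total element count over trainable weight grids (batch-norm scale/shift
    included; running statistics excluded)."""
    return handle.trainable_parameter_count
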