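"""Post-hoc voxel-level explanation methods for image classifiers.

Three standard attribution techniques are provided as comparators to the
WSUnet's intrinsic voxel-probability map:

- **Grad-CAM**: channel weights are the spatial means of the gradient of
  the image-level score with respect to a convolutional layer's
  activations; the map is the rectified channel-weighted activation sum at
  the layer's native resolution.
- **Integrated gradients**: the input-gradient averaged along a straight
  path from a baseline (default: all-zeros) to the input, scaled by the
  input-baseline difference; 10 path steps by default.
- **Occlusion sensitivity**: the drop in the image-level score when a
  square window (default width 10) is replaced by a fill value, averaged
  over every window covering a pixel.

Plus nearest-neighbour upsampling of coarse maps to the input resolution
and the joint min-max normalisation used to display a set of maps on a
shared colour scale.  Any model exposing ``predict_image`` /
``input_gradient`` / ``activations_and_gradients`` can be explained; the
package's own handles satisfy this contract.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "SaliencyMap",
    "OcclusionConfig",
    "IGConfig",
    "grad_cam",
    "upsample_nearest",
    "integrated_gradients",
    "occlusion_sensitivity",
    "wsunet_voxel_map",
    "normalise_joint",
    "save_map",
]


@dataclass
class SaliencyMap:
    """An input-aligned relevance grid with provenance metadata."""

    values: np.ndarray
    method: str  # 'wsunet_voxels' | 'gradcam' | 'integrated_gradients' | 'occlusion'
    source_layer: Optional[int] = None
    native_shape: Optional[Tuple[int, int]] = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("saliency values must be finite")
        if self.native_shape is None:
            self.native_shape = self.values.shape


@dataclass(frozen=True)
class OcclusionConfig:
    window_width: int = 10
    stride: int = 1
    fill_value: float = 0.0  # scaled intensity of the occluding square (~water)

    def __post_init__(self):
        if self.window_width < 1:
            raise ValueError("window_width must be >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass(frozen=True)
class IGConfig:
    steps: int = 10
    baseline: Optional[np.ndarray] = None  # default: all-zeros input

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be >= 1")


def _patch_pixels(patch) -> np.ndarray:
    """Accept either a Patch or a bare 2D array."""
    return np.asarray(getattr(patch, "pixels", patch), dtype=np.float32)


def grad_cam(handle, layer_index: int, patch) -> SaliencyMap:
    """Grad-CAM at a catalogue layer with a spatial feature grid.

    Channel weights are spatial means of d(image score)/d(activations);
    negative contributions in the weighted sum are rectified to zero.  The
    map stays at the layer's native resolution; use
    :func:`upsample_nearest` to reach the input grid.
    """
    x = _patch_pixels(patch)[None, ..., None]
    acts, grads = handle.activations_and_gradients(x, layer_index)
    if acts.ndim != 4:
        raise ValueError("Grad-CAM requires a spatial feature grid")
    a, g = acts[0], grads[0]
    weights = g.mean(axis=(0, 1))
    cam = np.maximum((a * weights).sum(axis=-1), 0.0)
    return SaliencyMap(cam, "gradcam", source_layer=layer_index,
                       native_shape=cam.shape)


def upsample_nearest(smap: SaliencyMap, target_shape: Tuple[int, int]) -> SaliencyMap:
    """Nearest-neighbour upsampling; the set of distinct values is preserved."""
    h, w = smap.values.shape
    th, tw = target_shape
    if th < h or tw < w:
        raise ValueError("upsampling target must be at least the native shape")
    rows = (np.arange(th) * h) // th
    cols = (np.arange(tw) * w) // tw
    vals = smap.values[np.ix_(rows, cols)]
    return SaliencyMap(vals, smap.method, smap.source_layer, smap.native_shape)


def integrated_gradients(handle, patch, config: IGConfig = IGConfig()) -> SaliencyMap:
    """Path-integrated input gradients at full input resolution.

    attribution = (x - x0) * mean_{k=1..K} grad f(x0 + (k/K)(x - x0)).
    """
    x = _patch_pixels(patch)
    baseline = np.zeros_like(x) if config.baseline is None else np.asarray(
        config.baseline, dtype=x.dtype)
    if baseline.shape != x.shape:
        raise ValueError("baseline shape must match the input")
    diff = x - baseline
    batch = np.stack([
        baseline + (k / config.steps) * diff for k in range(1, config.steps + 1)
    ])[..., None]
    grads = handle.input_gradient(batch)[..., 0]
    attribution = diff * grads.mean(axis=0)
    return SaliencyMap(attribution, "integrated_gradients",
                       native_shape=attribution.shape)


def occlusion_sensitivity(handle, patch,
                          config: OcclusionConfig = OcclusionConfig(),
                          batch_size: int = 64) -> SaliencyMap:
    """Score drop under a sliding occluding square, averaged per pixel.

    Window top-left corners run over the stride grid; each pixel's value is
    the mean of f(x) - f(x occluded) over all windows covering it, and
    exactly 0 for pixels no window reaches.
    """
    x = _patch_pixels(patch)
    h, w = x.shape
    k = config.window_width
    if k > min(h, w):
        raise ValueError("occlusion window larger than the patch")
    tops = range(0, h - k + 1, config.stride)
    lefts = range(0, w - k + 1, config.stride)
    positions = [(i, j) for i in tops for j in lefts]

    base = float(np.asarray(handle.predict_image(x[None, ..., None]))[0])
    drops = np.empty(len(positions))
    for start in range(0, len(positions), batch_size):
        chunk = positions[start:start + batch_size]
        xb = np.repeat(x[None], len(chunk), axis=0)
        for b, (i, j) in enumerate(chunk):
            xb[b, i:i + k, j:j + k] = config.fill_value
        scores = np.asarray(handle.predict_image(xb[..., None]))
        drops[start:start + len(chunk)] = base - scores

    total = np.zeros((h, w))
    count = np.zeros((h, w))
    for (i, j), d in zip(positions, drops):
        total[i:i + k, j:j + k] += d
        count[i:i + k, j:j + k] += 1
    with np.errstate(invalid="ignore"):
        vals = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    return SaliencyMap(vals, "occlusion", native_shape=vals.shape)


def wsunet_voxel_map(handle, patch) -> SaliencyMap:
    """The WSUnet's own voxel-probability map as a saliency map.

    Its maximum equals the image-level prediction exactly — the causal
    link between explanation and decision that post-hoc methods lack.
    """
    x = _patch_pixels(patch)[None, ..., None]
    vox = handle.predict_voxels(x)[0]
    return SaliencyMap(vox, "wsunet_voxels", native_shape=vox.shape)


def normalise_joint(maps: Sequence[SaliencyMap]) -> List[SaliencyMap]:
    """Affine rescaling of a set of same-method maps to [0, 1] using the
    min/max pooled across all of them (display only; metrics use raw
    values).  All-constant inputs yield all-zero maps with a warning."""
    if not maps:
        raise ValueError("need at least one map")
    methods = {m.method for m in maps}
    if len(methods) > 1:
        raise ValueError(f"maps mix methods: {sorted(methods)}")
    lo = min(float(m.values.min()) for m in maps)
    hi = max(float(m.values.max()) for m in maps)
    if hi == lo:
        warnings.warn("all pooled saliency values identical; returning zeros")
        return [SaliencyMap(np.zeros_like(m.values, dtype=float), m.method,
                            m.source_layer, m.native_shape) for m in maps]
    return [SaliencyMap((m.values - lo) / (hi - lo), m.method,
                        m.source_layer, m.native_shape) for m in maps]


def save_map(smap: SaliencyMap, path, patch=None) -> None:
    """Write the raw array (npy), a JSON sidecar, and a PNG overlay if the
    source patch is provided."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path.with_suffix(".npy"), smap.values)
    sidecar = {"method": smap.method, "source_layer": smap.source_layer,
               "native_shape": list(smap.native_shape)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    if patch is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(_patch_pixels(patch), cmap="gray")
        ax.imshow(smap.values, cmap="inferno", alpha=0.5)
        ax.set_axis_off()
        ax.set_title(smap.method)
        fig.savefig(path.with_suffix(".png"), dpi=100, bbox_inches="tight")
        plt.close(fig)
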