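"""Weakly labelled 2D patch sampling from labelled volumes.

Implements the dataset-construction protocol for weakly supervised
training on chest CT: intensities are rescaled from Hounsfield units by a
factor of 0.001; per subject, 40 axial patches of 128x128 voxels are
sampled with centrepoints drawn uniformly (with replacement) from the
tumour voxels, and 40 from the contralateral lung by reflecting tumour
voxels across the sagittal midplane and offsetting them by independent
uniform integer draws of up to +-15 voxels axially and +-75 voxels
coronally and sagittally.  Every patch is labelled positive if and only if
its mask window contains at least one tumour voxel — contralateral patches
are *not* assumed negative.

Voxel masks ride along with each patch for evaluation only; the training
module never shows them to the optimiser.

Conventions (the source protocol is silent on these):
- the "centrepoint" sits at (height/2, width/2) of the window with 0-based
  indices and half-open extents [c-64, c+64);
- centres are clamped so the window always lies fully inside the volume,
  avoiding padding that could leak label information;
- the sagittal reflection maps index j to (W-1-j), an exact involution on
  the integer grid.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyDatasetError, NoTumourError
from .phantom import LabelledVolume

__all__ = [
    "PatchSamplingConfig",
    "Patch",
    "PatchDataset",
    "rescale_hu",
    "label_patch",
    "sample_tumour_patches",
    "sample_contralateral_patches",
    "assemble_dataset",
    "read_dicom_series",
    "write_dataset",
    "read_dataset",
]


@dataclass(frozen=True)
class PatchSamplingConfig:
    patch_shape: Tuple[int, int] = (128, 128)
    n_tumour: int = 40
    n_contralateral: int = 40
    offset_axial: int = 15
    offset_coronal: int = 75
    offset_sagittal: int = 75
    hu_scale: float = 0.001
    seed: int = 0

    def __post_init__(self):
        if self.n_tumour < 0 or self.n_contralateral < 0:
            raise ConfigurationError("patch counts must be >= 0")
        if min(self.offset_axial, self.offset_coronal, self.offset_sagittal) < 0:
            raise ConfigurationError("offsets must be >= 0")
        if any(d % 2 for d in self.patch_shape):
            raise ConfigurationError("patch dimensions must be even")


@dataclass
class Patch:
    """One 2D axial patch with image-level label and held-out voxel mask."""

    pixels: np.ndarray
    label: int
    mask: Optional[np.ndarray]  # None only for mask-free (training-side) loads
    subject_id: str
    centre: Tuple[int, int, int]  # (axial, coronal, sagittal), post-clamp
    origin: str  # 'tumour_centred' | 'contralateral'
    source_voxel: Optional[Tuple[int, int, int]] = None  # tumour voxel behind this sample
    proposed_centre: Optional[Tuple[int, int, int]] = None  # pre-clamp centre

    def __post_init__(self):
        if self.mask is None:
            return
        if self.pixels.shape != self.mask.shape:
            raise ValueError("pixels and mask shapes differ")
        if self.label != int(self.mask.max() > 0):
            raise ValueError("label inconsistent with mask window")


@dataclass
class PatchDataset:
    patches: List[Patch]
    sampling_config: PatchSamplingConfig
    provenance: Dict[str, Tuple[int, int]]  # subject -> (n_tumour, n_contralateral)

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def subject_ids(self) -> List[str]:
        seen: List[str] = []
        for p in self.patches:
            if p.subject_id not in seen:
                seen.append(p.subject_id)
        return seen

    def subset(self, subject_ids: Sequence[str]) -> "PatchDataset":
        keep = set(subject_ids)
        sel = [p for p in self.patches if p.subject_id in keep]
        prov = {s: c for s, c in self.provenance.items() if s in keep}
        return PatchDataset(sel, self.sampling_config, prov)

    def arrays(self) -> Tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
        """(pixels (N,H,W,1) float32, labels (N,), masks (N,H,W) uint8).

        Masks are ``None`` for mask-free (training-side) datasets.
        """
        x = np.stack([p.pixels for p in self.patches]).astype(np.float32)[..., None]
        y = np.array([p.label for p in self.patches], dtype=np.float32)
        if any(p.mask is None for p in self.patches):
            return x, y, None
        m = np.stack([p.mask for p in self.patches]).astype(np.uint8)
        return x, y, m


def rescale_hu(volume: LabelledVolume, hu_scale: float = 0.001) -> LabelledVolume:
    """Multiply intensities by ``hu_scale`` (1000 HU -> 1.0); mask unchanged."""
    return LabelledVolume(
        volume.intensity * np.float32(hu_scale),
        volume.tumour_mask,
        volume.subject_id,
        volume.lesion_side,
    )


def label_patch(mask_window: np.ndarray) -> int:
    """1 iff the window contains any tumour voxel."""
    return int(np.asarray(mask_window).max(initial=0) > 0)


def _subject_rng(config: PatchSamplingConfig, volume: LabelledVolume, stream: int):
    ent = zlib.crc32(volume.subject_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([config.seed, ent, stream]))


def _clamp_centre(c, shape, patch_shape) -> Tuple[int, int, int]:
    if patch_shape[0] > shape[1] or patch_shape[1] > shape[2]:
        raise ConfigurationError(
            f"patch shape {patch_shape} exceeds in-plane volume dims {shape[1:]}")
    hh, hw = patch_shape[0] // 2, patch_shape[1] // 2
    z = int(np.clip(c[0], 0, shape[0] - 1))
    y = int(np.clip(c[1], hh, shape[1] - patch_shape[0] + hh))
    x = int(np.clip(c[2], hw, shape[2] - patch_shape[1] + hw))
    return z, y, x


def _extract(volume: LabelledVolume, centre, patch_shape):
    z, y, x = centre
    hh, hw = patch_shape[0] // 2, patch_shape[1] // 2
    sl = (z, slice(y - hh, y - hh + patch_shape[0]), slice(x - hw, x - hw + patch_shape[1]))
    return volume.intensity[sl], volume.tumour_mask[sl]


def _tumour_voxels(volume: LabelledVolume) -> np.ndarray:
    vox = np.argwhere(volume.tumour_mask > 0)
    if len(vox) == 0:
        raise NoTumourError(f"subject {volume.subject_id} has no tumour voxels")
    return vox


def sample_tumour_patches(volume: LabelledVolume, config: PatchSamplingConfig) -> List[Patch]:
    """``n_tumour`` patches centred (up to clamping) on uniformly drawn
    tumour voxels.  All returned patches carry label 1 by construction."""
    vox = _tumour_voxels(volume)
    rng = _subject_rng(config, volume, stream=0)
    out: List[Patch] = []
    for _ in range(config.n_tumour):
        src = tuple(int(v) for v in vox[rng.integers(len(vox))])
        centre = _clamp_centre(src, volume.shape, config.patch_shape)
        pix, msk = _extract(volume, centre, config.patch_shape)
        out.append(Patch(pix.copy(), label_patch(msk), msk.copy(), volume.subject_id,
                         centre, "tumour_centred", source_voxel=src, proposed_centre=src))
    return out


def sample_contralateral_patches(volume: LabelledVolume, config: PatchSamplingConfig) -> List[Patch]:
    """``n_contralateral`` patches centred on sagittally mirrored tumour
    voxels with independent uniform integer offsets, then clamped.

    Labels follow :func:`label_patch`; a contralateral window that happens
    to contain tumour voxels is kept and labelled positive.
    """
    vox = _tumour_voxels(volume)
    rng = _subject_rng(config, volume, stream=1)
    W = volume.shape[2]
    out: List[Patch] = []
    for _ in range(config.n_contralateral):
        src = tuple(int(v) for v in vox[rng.integers(len(vox))])
        mirrored = (src[0], src[1], W - 1 - src[2])
        offs = (
            int(rng.integers(-config.offset_axial, config.offset_axial + 1)),
            int(rng.integers(-config.offset_coronal, config.offset_coronal + 1)),
            int(rng.integers(-config.offset_sagittal, config.offset_sagittal + 1)),
        )
        proposed = tuple(m + o for m, o in zip(mirrored, offs))
        centre = _clamp_centre(proposed, volume.shape, config.patch_shape)
        pix, msk = _extract(volume, centre, config.patch_shape)
        out.append(Patch(pix.copy(), label_patch(msk), msk.copy(), volume.subject_id,
                         centre, "contralateral", source_voxel=src, proposed_centre=proposed))
    return out


def assemble_dataset(volumes: Sequence[LabelledVolume],
                     config: PatchSamplingConfig = PatchSamplingConfig()) -> PatchDataset:
    """Rescale, sample and concatenate patches in subject order.

    Subjects without tumour voxels are skipped; if no subject yields
    patches the dataset is empty and an error is raised.
    """
    patches: List[Patch] = []
    provenance: Dict[str, Tuple[int, int]] = {}
    for vol in volumes:
        scaled = rescale_hu(vol, config.hu_scale)
        try:
            tum = sample_tumour_patches(scaled, config)
            con = sample_contralateral_patches(scaled, config)
        except NoTumourError:
            continue
        patches.extend(tum)
        patches.extend(con)
        provenance[vol.subject_id] = (len(tum), len(con))
    if not patches:
        raise EmptyDatasetError("no patches could be sampled from the given volumes")
    return PatchDataset(patches, config, provenance)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_dicom_series(series_dir) -> np.ndarray:
    """Read a DICOM series directory into a HU volume (axial, coronal, sagittal).

    Slices are sorted by the z component of ImagePositionPatient (falling
    back to InstanceNumber) and the rescale slope/intercept is applied.
    Only intensities are read; masks come from NIfTI (see
    :func:`wsunet.phantom.read_volume`).
    """
    import pydicom

    files = sorted(Path(series_dir).glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no .dcm files in {series_dir}")
    slices = [pydicom.dcmread(str(f)) for f in files]

    def key(ds):
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None:
            return float(pos[2])
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=key)
    arrs = []
    for ds in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arrs.append(ds.pixel_array.astype(np.float32) * slope + intercept)
    return np.stack(arrs, axis=0)


def write_dataset(dataset: PatchDataset, out_dir) -> Path:
    """Write patches as arrays plus a CSV manifest.

    Images/labels and masks live in separate files so that a training run
    can load inputs without ever touching the voxel masks.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    x, y, m = dataset.arrays()
    np.save(out_dir / "images.npy", x)
    np.save(out_dir / "masks.npy", m)
    rows = []
    for p in dataset.patches:
        rows.append({
            "subject_id": p.subject_id,
            "centre_axial": p.centre[0], "centre_coronal": p.centre[1],
            "centre_sagittal": p.centre[2],
            "origin": p.origin, "label": p.label,
            "mask_positive_voxels": int(p.mask.sum()),
        })
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    return out_dir


def read_dataset(in_dir, config: Optional[PatchSamplingConfig] = None) -> PatchDataset:
    in_dir = Path(in_dir)
    x = np.load(in_dir / "images.npy")
    m = np.load(in_dir / "masks.npy")
    man = pd.read_csv(in_dir / "manifest.csv")
    cfg = config or PatchSamplingConfig(patch_shape=x.shape[1:3])
    patches = []
    prov: Dict[str, Tuple[int, int]] = {}
    for i, row in man.iterrows():
        p = Patch(x[i, ..., 0], int(row["label"]), m[i], row["subject_id"],
                  (int(row["centre_axial"]), int(row["centre_coronal"]),
                   int(row["centre_sagittal"])), row["origin"])
        patches.append(p)
        t, c = prov.get(p.subject_id, (0, 0))
        prov[p.subject_id] = (t + (p.origin == "tumour_centred"),
                              c + (p.origin == "contralateral"))
    return PatchDataset(patches, cfg, prov)
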