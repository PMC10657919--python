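"""Synthetic CT-like thorax phantoms with tumour masks.

The generator emulates the structure the patch sampler and the weakly
supervised training protocol need from real chest CT: a soft-tissue body on
an air background, two sagittally mirror-symmetric low-attenuation lung
fields, and one to a few "blobby" lesions placed strictly inside one lung
(the other lung stays lesion-free, so contralateral mirror sampling yields
negative patches).  Intensities are piecewise-constant tissue means in
Hounsfield units plus Gaussian noise; optional rib-like high-intensity arcs
act as confounders for saliency experiments.

Everything is deterministic: identical (config, subject_id) yields
bit-identical volumes.  Tissue noise and lesion placement draw from
separate child RNG streams, so regenerating a subject with lesions disabled
reproduces the identical lesion-free background.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Tuple

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, InfeasibleGeometryError

__all__ = [
    "PhantomConfig",
    "LabelledVolume",
    "generate_volume",
    "generate_cohort",
    "write_volume",
    "read_volume",
]

AIR_HU = -1000.0


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and intensity statistics of the synthetic thorax.

    Axis order is (axial, coronal, sagittal).  Intensity means are in
    Hounsfield units; lesions are markedly denser than lung parenchyma but
    close to soft tissue, as for solid pulmonary tumours.
    """

    volume_shape: Tuple[int, int, int] = (32, 256, 256)
    lung_intensity_hu: float = -800.0
    body_intensity_hu: float = 40.0
    lesion_intensity_hu: float = -50.0
    noise_sd_hu: float = 20.0
    lesion_count_range: Tuple[int, int] = (1, 3)
    lesion_radius_range_vox: Tuple[float, float] = (4.0, 8.0)
    confounder_ribs: bool = False
    seed: int = 0

    def __post_init__(self):
        if any(s < 16 for s in self.volume_shape):
            raise ConfigurationError("volume_shape components must be >= 16")
        lo, hi = self.lesion_count_range
        if lo > hi or lo < 0:
            raise ConfigurationError("lesion_count_range must be a non-empty range of counts")
        rlo, rhi = self.lesion_radius_range_vox
        if rlo > rhi or rlo <= 0:
            raise ConfigurationError("lesion_radius_range_vox must be a non-empty positive range")
        if self.noise_sd_hu < 0:
            raise ConfigurationError("noise_sd_hu must be >= 0")


@dataclass
class LabelledVolume:
    """A 3D intensity grid with an aligned binary tumour mask."""

    intensity: np.ndarray
    tumour_mask: np.ndarray
    subject_id: str
    lesion_side: Optional[str] = None  # 'left' | 'right' | None

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity)
        self.tumour_mask = np.asarray(self.tumour_mask)
        if self.intensity.shape != self.tumour_mask.shape:
            raise ValueError("intensity and tumour_mask shapes differ")
        vals = np.unique(self.tumour_mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("tumour_mask must be binary")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.intensity.shape


def _subject_entropy(subject_id: str) -> int:
    return zlib.crc32(subject_id.encode("utf-8"))


def _lung_geometry(shape):
    """Centres and semi-axes of the two mirror-symmetric lung ellipsoids."""
    z, y, x = shape
    semi = np.array([0.42 * z, 0.32 * y, 0.16 * x])
    mid = (x - 1) / 2.0
    offset = 0.22 * x
    centre_left = np.array([(z - 1) / 2.0, (y - 1) / 2.0, mid - offset])
    return centre_left, semi, mid


def _ellipsoid_mask(shape, centre, semi) -> np.ndarray:
    zz = (np.arange(shape[0])[:, None, None] - centre[0]) / semi[0]
    yy = (np.arange(shape[1])[None, :, None] - centre[1]) / semi[1]
    xx = (np.arange(shape[2])[None, None, :] - centre[2]) / semi[2]
    return zz**2 + yy**2 + xx**2 <= 1.0


def lung_fields(config: PhantomConfig) -> Tuple[np.ndarray, np.ndarray]:
    """(left, right) lung masks; the right lung is the exact sagittal mirror
    of the left, so the pair is symmetric on the integer grid."""
    centre_left, semi, _ = _lung_geometry(config.volume_shape)
    left = _ellipsoid_mask(config.volume_shape, centre_left, semi)
    right = left[:, :, ::-1]
    return left, right


def _body_mask(shape) -> np.ndarray:
    z, y, x = shape
    cy, cx = (y - 1) / 2.0, (x - 1) / 2.0
    yy = (np.arange(y)[:, None] - cy) / (0.45 * y)
    xx = (np.arange(x)[None, :] - cx) / (0.45 * x)
    plane = yy**2 + xx**2 <= 1.0
    return np.broadcast_to(plane, shape).copy()


def _rib_mask(shape) -> np.ndarray:
    """Rib-like arcs: thin shells around both lungs on alternating slices."""
    centre_left, semi, _ = _lung_geometry(shape)
    zz = (np.arange(shape[0])[:, None, None] - centre_left[0]) / semi[0]
    yy = (np.arange(shape[1])[None, :, None] - centre_left[1]) / semi[1]
    xx = (np.arange(shape[2])[None, None, :] - centre_left[2]) / (semi[2] * 1.12)
    rho = np.sqrt(zz**2 + yy**2 + xx**2)
    shell = (rho > 1.12) & (rho < 1.28)
    shell = shell | shell[:, :, ::-1]
    keep = (np.arange(shape[0]) % 4 < 2)[:, None, None]
    return shell & keep


def _rasterise_lesion(shape, centre, radii, rng) -> np.ndarray:
    """Union of 1-3 jittered ellipsoids around ``centre``, morphologically
    closed to give a smooth blobby boundary.  Work happens in a local
    bounding box for speed."""
    n_sub = int(rng.integers(1, 4))
    parts = [(centre, radii)]
    for _ in range(n_sub - 1):
        off = rng.uniform(-0.5, 0.5, size=3) * radii
        sub_r = radii * rng.uniform(0.6, 1.0, size=3)
        parts.append((centre + off, np.maximum(sub_r, 1.0)))

    pad = 2  # room for the closing operator
    lo = np.maximum(np.floor([min(c[a] - r[a] for c, r in parts) for a in range(3)]).astype(int) - pad, 0)
    hi = np.minimum(np.ceil([max(c[a] + r[a] for c, r in parts) for a in range(3)]).astype(int) + pad + 1,
                    np.asarray(shape))
    box = np.zeros(hi - lo, dtype=bool)
    for c, r in parts:
        zz = (np.arange(lo[0], hi[0])[:, None, None] - c[0]) / r[0]
        yy = (np.arange(lo[1], hi[1])[None, :, None] - c[1]) / r[1]
        xx = (np.arange(lo[2], hi[2])[None, None, :] - c[2]) / r[2]
        box |= zz**2 + yy**2 + xx**2 <= 1.0
    box = ndimage.binary_closing(box, structure=ndimage.generate_binary_structure(3, 1))
    out = np.zeros(shape, dtype=bool)
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = box
    return out


def generate_volume(config: PhantomConfig, subject_id: str) -> LabelledVolume:
    """Generate one labelled phantom volume.

    All lesions of a subject are placed in a single lung, leaving the other
    lung lesion-free so that contralateral sampling yields negatives.

    Raises
    ------
    InfeasibleGeometryError
        If the requested lesion radii cannot fit inside a lung field.
    """
    ss = np.random.SeedSequence([config.seed, _subject_entropy(subject_id)])
    rng_noise, rng_lesion = [np.random.default_rng(c) for c in ss.spawn(2)]
    shape = config.volume_shape

    body = _body_mask(shape)
    left, right = lung_fields(config)
    lungs = left | right

    intensity = np.full(shape, AIR_HU, dtype=np.float32)
    intensity[body] = config.body_intensity_hu
    intensity[lungs] = config.lung_intensity_hu
    if config.confounder_ribs:
        ribs = _rib_mask(shape) & body & ~lungs
        intensity[ribs] = 700.0
    if config.noise_sd_hu > 0:
        intensity += rng_noise.normal(0.0, config.noise_sd_hu, size=shape).astype(np.float32)

    # -- lesions ---------------------------------------------------------
    n_lesions = int(rng_lesion.integers(config.lesion_count_range[0],
                                        config.lesion_count_range[1] + 1))
    mask = np.zeros(shape, dtype=np.uint8)
    lesion_side: Optional[str] = None
    if n_lesions > 0:
        lesion_side = "left" if rng_lesion.random() < 0.5 else "right"
        centre_left, semi, mid = _lung_geometry(shape)
        lung_centre = centre_left.copy()
        if lesion_side == "right":
            lung_centre[2] = 2 * mid - lung_centre[2]
        lung_mask = left if lesion_side == "left" else right
        for _ in range(n_lesions):
            base_r = rng_lesion.uniform(*config.lesion_radius_range_vox)
            radii = base_r * rng_lesion.uniform(0.7, 1.2, size=3)
            margin = semi - radii - 1.0
            if np.any(margin <= 0):
                raise InfeasibleGeometryError(
                    f"lesion radii {radii} do not fit inside lung semi-axes {semi}")
            # uniform draw inside the shrunken lung ellipsoid
            u = rng_lesion.normal(size=3)
            u /= np.linalg.norm(u)
            u *= rng_lesion.random() ** (1.0 / 3.0)
            centre = lung_centre + u * margin
            lesion = _rasterise_lesion(shape, centre, radii, rng_lesion) & lung_mask
            mask[lesion] = 1
            intensity[lesion] = config.lesion_intensity_hu
            if config.noise_sd_hu > 0:
                intensity[lesion] += rng_lesion.normal(
                    0.0, config.noise_sd_hu, size=int(lesion.sum())).astype(np.float32)

    return LabelledVolume(intensity, mask, subject_id, lesion_side)


def generate_cohort(config: PhantomConfig, n_subjects: int) -> List[LabelledVolume]:
    """Generate ``n_subjects`` phantoms with distinct, stable subject ids."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    return [generate_volume(config, f"S{i:04d}") for i in range(n_subjects)]


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def write_volume(volume: LabelledVolume, out_dir) -> Tuple[Path, Path]:
    """Write intensity and mask as a NIfTI pair with identical geometry."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    img_path = out_dir / f"{volume.subject_id}_image.nii.gz"
    mask_path = out_dir / f"{volume.subject_id}_mask.nii.gz"
    nib.save(nib.Nifti1Image(volume.intensity.astype(np.float32), affine), img_path)
    nib.save(nib.Nifti1Image(volume.tumour_mask.astype(np.uint8), affine), mask_path)
    return img_path, mask_path


def read_volume(image_path, mask_path, subject_id: Optional[str] = None) -> LabelledVolume:
    image_path, mask_path = Path(image_path), Path(mask_path)
    if subject_id is None:
        subject_id = image_path.name.split("_image")[0]
    intensity = np.asarray(nib.load(image_path).dataobj, dtype=np.float32)
    mask = (np.asarray(nib.load(mask_path).dataobj) > 0.5).astype(np.uint8)
    return LabelledVolume(intensity, mask, subject_id)
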