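"""Volume data model, NIfTI/MetaImage I/O, and resampling to a common voxel grid.

All geometry is done in mm world space. Arrays are indexed (x, y, z) with z the
slice (cranio-caudal) axis, 0-based indices, voxels addressed by their centers:
world = origin + index * spacing.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "ImageVolume",
    "RoiMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "resample",
    "world_to_voxel",
    "voxel_to_world",
]

_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


def _check_geometry(spacing, origin) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    spacing = tuple(float(s) for s in spacing)
    origin = tuple(float(o) for o in origin)
    if len(spacing) != 3 or len(origin) != 3:
        raise ValueError("spacing and origin must be 3-vectors")
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"spacing must be strictly positive, got {spacing}")
    return spacing, origin


@dataclass
class ImageVolume:
    """A 3D scalar grid in Hounsfield units with mm geometry.

    Parameters
    ----------
    intensities : ndarray, shape (nx, ny, nz)
        Voxel intensities in HU.
    spacing : 3-tuple of float
        Voxel spacing in mm per axis, strictly positive.
    origin : 3-tuple of float
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        self.spacing, self.origin = _check_geometry(self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def extent_mm(self) -> np.ndarray:
        """Physical size of the grid (mm) counted as n * spacing per axis."""
        return np.asarray(self.shape) * np.asarray(self.spacing)


@dataclass
class RoiMask:
    """A boolean grid aligned to a parent :class:`ImageVolume`.

    ``kind`` tags which of the six ROI constructions produced the mask;
    ``is_2d`` flags single-slice ROIs so shape features are skipped.
    """

    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    kind: str = "generic"
    sub_label: str | None = None
    is_2d: bool = False
    degenerate: bool = False

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be a 3D array")
        self.spacing, self.origin = _check_geometry(self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    def count(self) -> int:
        return int(self.mask.sum())

    def volume_mm3(self) -> float:
        return self.count() * float(np.prod(self.spacing))

    def voxel_centers_mm(self) -> np.ndarray:
        """World coordinates (mm) of all included voxel centers, (n, 3)."""
        idx = np.argwhere(self.mask)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)


def _check_path(path) -> Path:
    path = Path(path)
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise ValueError(
            f"unsupported format {path.suffix!r}; supported: {_SUPPORTED_SUFFIXES}"
        )
    return path


def _to_sitk(arr: np.ndarray, spacing, origin) -> sitk.Image:
    # SimpleITK arrays are (z, y, x); ours are (x, y, z)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, tuple, tuple]:
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise ValueError(
            "oblique/non-identity orientations are not supported; "
            f"direction matrix was {direction.tolist()}"
        )
    spacing = img.GetSpacing()
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive voxel spacing in file: {spacing}")
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return arr, tuple(spacing), tuple(img.GetOrigin())


def read_volume(path) -> ImageVolume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume."""
    path = _check_path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
    return ImageVolume(arr.astype(np.float32), spacing, origin)


def write_volume(vol: ImageVolume, path) -> None:
    path = _check_path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(_to_sitk(vol.intensities.astype(np.float32), vol.spacing, vol.origin), str(path))


def write_mask(mask: RoiMask, path, ggo: RoiMask | None = None) -> None:
    """Write a mask as integer labels: 1 = ROI, 2 = GGO sub-ROI (if given)."""
    path = _check_path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    labels = mask.mask.astype(np.uint8)
    if ggo is not None:
        labels = labels + 2 * ggo.mask.astype(np.uint8)
    sitk.WriteImage(_to_sitk(labels, mask.spacing, mask.origin), str(path))


def read_mask(path, label: int = 1, kind: str = "generic") -> RoiMask:
    path = _check_path(path)
    arr, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
    return RoiMask(arr == label, spacing, origin, kind=kind)


def resample(vol: ImageVolume, target_spacing) -> ImageVolume:
    """Resample to ``target_spacing`` (mm) with trilinear interpolation.

    The world-space extent is preserved to within one output voxel; the grid
    origin is unchanged.
    """
    target_spacing, _ = _check_geometry(target_spacing, vol.origin)
    out_shape = tuple(
        max(1, int(round(n * s / t)))
        for n, s, t in zip(vol.shape, vol.spacing, target_spacing)
    )
    if any(n <= 1 for n in vol.shape):
        raise ValueError(f"cannot resample a degenerate (single-voxel) axis: shape {vol.shape}")
    img = _to_sitk(vol.intensities.astype(np.float64), vol.spacing, vol.origin)
    out = sitk.Resample(
        img,
        size=[int(n) for n in out_shape],
        transform=sitk.Transform(),
        interpolator=sitk.sitkLinear,
        outputOrigin=vol.origin,
        outputSpacing=target_spacing,
        outputDirection=img.GetDirection(),
        defaultPixelValue=float(vol.intensities.min()),
    )
    arr, spacing, origin = _from_sitk(out)
    return ImageVolume(arr.astype(np.float32), spacing, origin)


def world_to_voxel(vol, point_mm) -> np.ndarray:
    """Continuous voxel index of a world point (voxel-center convention)."""
    return (np.asarray(point_mm, dtype=float) - np.asarray(vol.origin)) / np.asarray(vol.spacing)


def voxel_to_world(vol, index) -> np.ndarray:
    """World coordinate (mm) of a (possibly fractional) voxel index."""
    return np.asarray(index, dtype=float) * np.asarray(vol.spacing) + np.asarray(vol.origin)
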