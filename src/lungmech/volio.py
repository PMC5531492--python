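"""Volume I/O, mask handling and HU calibration.

Volumes are plain 3-D scalar grids in Hounsfield units with per-axis voxel
spacing and a world origin.  The coordinate convention used throughout the
package: voxel indices are 0-based and the world position of the *center*
of voxel (i, j, k) is ``origin + index * spacing`` (axis-aligned grids; no
direction matrix).  All geometry is in millimetres.

File formats are NIfTI (``.nii``/``.nii.gz``) and MetaImage
(``.mha``/``.mhd``), read and written through SimpleITK.  Note SimpleITK
stores arrays in (z, y, x) order; this module transposes so that
``ScalarVolume.data[i, j, k]`` indexes (x, y, z) and ``spacing``/``origin``
are in (x, y, z) order, matching the on-disk header.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import SimpleITK as sitk

__all__ = [
    "ScalarVolume",
    "MaskSet",
    "CalibrationROIs",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_deformation_field",
    "write_deformation_field",
    "calibrate_hu",
    "HU_AIR",
    "HU_TISSUE",
]

#: HU anchors: air in the middle of the trachea, blood/soft tissue in the aorta.
HU_AIR = -1000.0
HU_TISSUE = 55.0

_SUPPORTED_EXT = (".nii", ".nii.gz", ".mha", ".mhd")


class VolumeFormatError(ValueError):
    """Unreadable or unsupported volume file."""


class VolumeMetadataError(ValueError):
    """Header present but geometric metadata missing or invalid."""


class CalibrationError(ValueError):
    """Degenerate calibration ROIs (equal mean intensities)."""


@dataclass
class ScalarVolume:
    """A 3-D scalar image in HU on a regular axis-aligned grid.

    Parameters
    ----------
    data
        3-D array, (x, y, z) index order.
    spacing
        Per-axis voxel edge length in mm, all > 0.
    origin
        World position (mm) of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeMetadataError(f"spacing must be 3 positive floats, got {self.spacing}")
        if not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Geometric volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates (mm) of voxel centers."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)
        )

    def same_grid(self, other: "ScalarVolume", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def with_data(self, data: np.ndarray) -> "ScalarVolume":
        return ScalarVolume(data, self.spacing, self.origin)


@dataclass
class MaskSet:
    """Binary lung mask plus optional lobe / airway / vessel masks.

    All masks must share the grid of the image they annotate; a shape or
    spacing mismatch is an error, never a silent resample.
    """

    lung: np.ndarray
    lobes: Optional[np.ndarray] = None
    airways: Optional[np.ndarray] = None
    vessels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.lung = np.asarray(self.lung).astype(bool)
        if self.lung.ndim != 3:
            raise ValueError("lung mask must be 3-D")
        if not self.lung.any():
            raise ValueError("lung mask is empty")
        for name in ("lobes", "airways", "vessels"):
            m = getattr(self, name)
            if m is None:
                continue
            m = np.asarray(m)
            if m.shape != self.lung.shape:
                raise ValueError(f"{name} mask shape {m.shape} != lung shape {self.lung.shape}")
            setattr(self, name, m.astype(bool) if name != "lobes" else m.astype(np.uint8))

    def combined(self) -> np.ndarray:
        """Union of lung, airway and vessel masks (the registration domain)."""
        out = self.lung.copy()
        if self.airways is not None:
            out |= self.airways
        if self.vessels is not None:
            out |= self.vessels
        return out

    def validate_against(self, vol: ScalarVolume) -> None:
        if self.lung.shape != vol.shape:
            raise ValueError(
                f"mask shape {self.lung.shape} does not match image shape {vol.shape}"
            )


@dataclass
class CalibrationROIs:
    """Voxel-index sets anchoring the HU scale: mid-trachea air and aortic blood."""

    trachea: np.ndarray  # (n, 3) integer voxel indices
    aorta: np.ndarray

    def __post_init__(self) -> None:
        self.trachea = np.atleast_2d(np.asarray(self.trachea, dtype=np.intp))
        self.aorta = np.atleast_2d(np.asarray(self.aorta, dtype=np.intp))
        if self.trachea.size == 0 or self.aorta.size == 0:
            raise ValueError("calibration ROIs must be non-empty")
        if self.trachea.shape[1] != 3 or self.aorta.shape[1] != 3:
            raise ValueError("ROIs must be (n, 3) voxel index arrays")
        t = set(map(tuple, self.trachea))
        a = set(map(tuple, self.aorta))
        if t & a:
            raise ValueError("trachea and aorta ROIs overlap")


def _check_path(path: str) -> None:
    low = str(path).lower()
    if not any(low.endswith(e) for e in _SUPPORTED_EXT):
        raise VolumeFormatError(
            f"unsupported extension for {path!r}; expected one of {_SUPPORTED_EXT}"
        )


def read_volume(path: str) -> ScalarVolume:
    """Read a NIfTI or MetaImage scalar volume; HU values are not modified."""
    _check_path(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - ITK error text varies
        raise VolumeFormatError(f"cannot read {path!r}: {exc}") from exc
    if img.GetDimension() != 3:
        raise VolumeFormatError(f"{path!r} is {img.GetDimension()}-D, expected 3-D")
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # (z,y,x) -> (x,y,z)
    spacing = img.GetSpacing()
    origin = img.GetOrigin()
    if any(s <= 0 for s in spacing):
        raise VolumeMetadataError(f"{path!r} has non-positive spacing {spacing}")
    return ScalarVolume(np.ascontiguousarray(data), spacing, origin)


def write_volume(vol: ScalarVolume, path: str) -> None:
    """Write a volume; float32 payloads round-trip bit-compatibly."""
    _check_path(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    try:
        sitk.WriteImage(img, str(path))
    except RuntimeError as exc:
        raise IOError(f"cannot write {path!r}: {exc}") from exc


def write_mask(mask: np.ndarray, like: ScalarVolume, path: str) -> None:
    """Write a binary/label mask as unsigned integers sharing the image header."""
    write_volume(like.with_data(np.asarray(mask).astype(np.uint8)), path)


def read_mask(path: str, like: Optional[ScalarVolume] = None) -> np.ndarray:
    """Read a mask volume; if `like` is given, enforce matching grid."""
    vol = read_volume(path)
    if like is not None:
        if vol.shape != like.shape or not np.allclose(vol.spacing, like.spacing):
            raise ValueError(
                f"mask grid {vol.shape}/{vol.spacing} does not match "
                f"image grid {like.shape}/{like.spacing}"
            )
    return vol.data.astype(bool) if vol.data.max() <= 1 else vol.data.astype(np.uint8)


def write_deformation_field(
    displacement: np.ndarray, spacing: Sequence[float], origin: Sequence[float], path: str
) -> None:
    """Write a per-voxel displacement field (mm) as a 4-D volume.

    Layout: (nx, ny, nz, 3) with the trailing axis the (x, y, z) displacement
    components on the reference grid.
    """
    disp = np.asarray(displacement, dtype=np.float64)
    if disp.ndim != 4 or disp.shape[3] != 3:
        raise ValueError(f"displacement must be (nx, ny, nz, 3), got {disp.shape}")
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(disp.transpose(2, 1, 0, 3)), isVector=True
    )
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    sitk.WriteImage(img, str(path))


def read_deformation_field(path: str) -> tuple[np.ndarray, tuple, tuple]:
    """Read a displacement field written by :func:`write_deformation_field`."""
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim != 4 or arr.shape[3] != 3:
        raise VolumeFormatError(f"{path!r} is not a 3-component vector field")
    return arr.transpose(2, 1, 0, 3), img.GetSpacing(), img.GetOrigin()


def calibrate_hu(vol: ScalarVolume, rois: CalibrationROIs) -> ScalarVolume:
    """Affine HU recalibration against two anatomical anchors.

    Solves for the map ``a*I + b`` that sends the mean intensity of the
    mid-trachea ROI to −1000 HU and the mean of the aortic ROI to 55 HU,
    and applies it to the whole volume.  The map is strictly monotone
    whenever the trachea mean is below the aorta mean, so intensity
    ordering is preserved; applying the calibration twice is a no-op.
    """
    ti, tj, tk = rois.trachea.T
    ai, aj, ak = rois.aorta.T
    mean_t = float(vol.data[ti, tj, tk].mean())
    mean_a = float(vol.data[ai, aj, ak].mean())
    if mean_t == mean_a:
        raise CalibrationError(
            f"trachea and aorta ROI means are equal ({mean_t}); cannot calibrate"
        )
    a = (HU_TISSUE - HU_AIR) / (mean_a - mean_t)
    b = HU_AIR - a * mean_t
    return vol.with_data(a * np.asarray(vol.data, dtype=np.float64) + b)
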