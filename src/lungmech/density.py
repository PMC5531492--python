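"""Air/tissue decomposition of CT voxels.

A voxel of geometric volume v with calibrated intensity I (HU) is split into
a tissue part and an air part by linear interpolation between the HU of pure
air (−1000) and pure soft tissue (+55):

    v_tissue = v * (I − HU_air) / (HU_tissue − HU_air),   v_air = v − v_tissue

with I clamped to [−1000, 55] first so fractions stay in [0, 1].  "Tissue"
means every non-air component: parenchymal tissue, blood, fluid, cells, and
any iodinated contrast.  The two parts are exactly additive per voxel and in
aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .volio import HU_AIR, HU_TISSUE, MaskSet, ScalarVolume

__all__ = [
    "tissue_fraction",
    "decompose",
    "global_volumes",
    "DensityDecomposition",
    "GlobalVolumes",
]


@dataclass
class DensityDecomposition:
    """Per-voxel air and tissue volumes (mm^3) over a lung mask."""

    tissue_volume: np.ndarray
    air_volume: np.ndarray
    mask: np.ndarray
    voxel_volume: float
    hu_air: float = HU_AIR
    hu_tissue: float = HU_TISSUE


@dataclass
class GlobalVolumes:
    """Whole-lung geometric, air and tissue volumes (mm^3); V = V_air + V_tissue."""

    V: float
    V_air: float
    V_tissue: float

    def as_dict(self) -> dict:
        return {"V_mm3": self.V, "V_air_mm3": self.V_air, "V_tissue_mm3": self.V_tissue}


def tissue_fraction(intensity) -> np.ndarray:
    """Fraction of a voxel occupied by non-air material, from calibrated HU.

    Intensities are clamped to [−1000, 55] before the linear map, so the
    result is in [0, 1], is non-decreasing in intensity, and is constant
    outside the clamp bounds.
    """
    arr = np.asarray(intensity, dtype=np.float64)
    if not np.isfinite(arr).all():
        raise ValueError("non-finite intensity passed to tissue_fraction")
    clamped = np.clip(arr, HU_AIR, HU_TISSUE)
    frac = (clamped - HU_AIR) / (HU_TISSUE - HU_AIR)
    if np.isscalar(intensity) or arr.ndim == 0:
        return float(frac)
    return frac


def decompose(
    vol: ScalarVolume, mask: MaskSet, exclude_vessels: bool = False
) -> DensityDecomposition:
    """Split each lung voxel into air and tissue volumes.

    Parameters
    ----------
    vol
        Calibrated HU volume.
    mask
        Mask set; aggregation domain is the lung mask, optionally minus
        vessel-mask voxels (`exclude_vessels=True`) to reduce the influence
        of intravascular contrast on parenchymal tissue estimates.
    """
    mask.validate_against(vol)
    domain = mask.lung.copy()
    if exclude_vessels and mask.vessels is not None:
        domain &= ~mask.vessels
    if not domain.any():
        raise ValueError("empty lung mask after exclusions")
    v = vol.voxel_volume
    vtis = v * tissue_fraction(vol.data)
    vair = v - vtis
    return DensityDecomposition(
        tissue_volume=vtis, air_volume=vair, mask=domain, voxel_volume=v
    )


def global_volumes(d: DensityDecomposition, mask: Optional[MaskSet] = None) -> GlobalVolumes:
    """Sum the decomposition over the lung domain.

    V is the geometric volume (voxel count times voxel volume); V_air and
    V_tissue sum the per-voxel parts, so V = V_air + V_tissue exactly.
    """
    domain = d.mask if mask is None else mask.lung
    n = int(domain.sum())
    if n == 0:
        raise ValueError("empty aggregation domain")
    v_tis = float(d.tissue_volume[domain].sum())
    v_air = float(d.air_volume[domain].sum())
    return GlobalVolumes(V=n * d.voxel_volume, V_air=v_air, V_tissue=v_tis)
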