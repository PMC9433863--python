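"""Volumetric image containers and NIfTI I/O.

CT volumes carry Hounsfield units (HU), PET volumes carry standardized
uptake values (SUV).  All downstream quantification assumes the CT and PET
of a patient live on one common grid (hardware-aligned PET/CT); there is no
registration or resampling here — a grid mismatch is an error the caller
must resolve upstream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "check_paired_grid",
]

#: modality tag -> voxel unit
_UNITS = {"CT": "HU", "PET": "SUV"}

#: spacing agreement tolerance for paired grids, in millimetres
SPACING_TOL_MM = 1e-6


@dataclass(frozen=True)
class ImageVolume:
    """A 3-D scalar grid with voxel spacing.

    Parameters
    ----------
    values
        3-D array of voxel values (HU for CT, SUV for PET).
    spacing
        Voxel edge lengths in millimetres, one per axis.
    modality
        ``"CT"`` or ``"PET"``; fixes the unit tag.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    modality: str
    units: str = field(init=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got {values.ndim} dimensions")
        if self.modality not in _UNITS:
            raise ValueError(f"modality must be one of {sorted(_UNITS)}, got {self.modality!r}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three strictly positive lengths, got {self.spacing!r}")
        n_bad = int(np.size(values) - np.isfinite(values).sum())
        if n_bad:
            raise ValueError(f"volume contains {n_bad} non-finite voxel(s)")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "units", _UNITS[self.modality])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in cubic millimetres."""
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class BinaryMask:
    """A 3-D boolean grid annotating a volume on the same grid."""

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got {values.ndim} dimensions")
        if values.dtype != bool:
            uniq = np.unique(values)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError("mask values must be boolean or 0/1")
            values = values.astype(bool)
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three strictly positive lengths, got {self.spacing!r}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def count(self) -> int:
        return int(self.values.sum())


def read_volume(path: str | os.PathLike, modality: str) -> ImageVolume:
    """Read a 3-D NIfTI file as an :class:`ImageVolume`.

    Values are taken verbatim (no rescaling beyond the NIfTI scl slope/
    intercept nibabel applies); spacing comes from the header pixdim.
    """
    img = nib.load(os.fspath(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image, got {data.ndim} dimensions")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(values=data, spacing=spacing, modality=modality)


def write_volume(volume: ImageVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI with a diagonal affine built from the spacing."""
    affine = np.diag((*volume.spacing, 1.0))
    img = nib.Nifti1Image(np.asarray(volume.values, dtype=np.float64), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, os.fspath(path))


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    """Write a mask as a 0/1 NIfTI volume."""
    affine = np.diag((*mask.spacing, 1.0))
    img = nib.Nifti1Image(mask.values.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, os.fspath(path))


def read_mask(path: str | os.PathLike) -> BinaryMask:
    """Read a 0/1 NIfTI file as a :class:`BinaryMask`."""
    img = nib.load(os.fspath(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D mask, got {data.ndim} dimensions")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return BinaryMask(values=data > 0.5, spacing=spacing)


def check_paired_grid(ct: ImageVolume | BinaryMask, pet: ImageVolume | BinaryMask) -> None:
    """Verify two images share one grid: equal shapes, spacings within 1e-6 mm.

    Raises ``ValueError`` on mismatch; a spacing mismatch signals that
    resampling is required upstream (out of scope here).
    """
    if ct.shape != pet.shape:
        raise ValueError(f"grid shape mismatch: {ct.shape} vs {pet.shape}")
    for a, b in zip(ct.spacing, pet.spacing):
        if abs(a - b) > SPACING_TOL_MM:
            raise ValueError(
                f"voxel spacing mismatch: {ct.spacing} vs {pet.spacing}; resample upstream"
            )
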