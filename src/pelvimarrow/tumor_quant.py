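"""Primary-lesion metabolic parameters: SUVmax, MTV and TLG.

The lesion is delineated by an ellipsoid volume of interest (VOI) given in
millimetres.  SUVmax is the maximum SUV inside the VOI; the metabolic
tumor volume (MTV) collects VOI voxels with SUV strictly above a fraction
(default 40%) of SUVmax; total lesion glycolysis (TLG) is MTV times the
mean SUV of the MTV region.  High-uptake structures that cannot be kept
out of the VOI (typically bladder urine) are removed by zeroing the PET
inside a separately drawn interference mask before measuring.

Voxel membership is decided by the voxel-center test: the center of voxel
(i, j, k) sits at world coordinate (i, j, k) * spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import BinaryMask, ImageVolume, check_paired_grid

__all__ = [
    "EllipsoidVOI",
    "TumorMetrics",
    "voi_mask",
    "suvmax",
    "segment_mtv",
    "tumor_metrics",
    "clear_interference",
]

#: default MTV threshold as a fraction of SUVmax (strict >)
MTV_FRACTION = 0.40


@dataclass(frozen=True)
class EllipsoidVOI:
    """Axis-aligned ellipsoid VOI: center and semi-axes in millimetres."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.center) != 3 or len(self.radii) != 3:
            raise ValueError("center and radii must be millimetre triples")
        if any(r <= 0 for r in self.radii):
            raise ValueError(f"radii must be strictly positive, got {self.radii!r}")


@dataclass(frozen=True)
class TumorMetrics:
    suvmax: float
    mtv: float  # cm^3
    tlg: float  # SUV * cm^3
    mtv_mean_suv: float
    threshold_fraction: float = MTV_FRACTION

    def __post_init__(self) -> None:
        if abs(self.tlg - self.mtv * self.mtv_mean_suv) > 1e-9 * max(1.0, abs(self.tlg)):
            raise ValueError("TLG inconsistent with MTV * mean SUV")


def voi_mask(voi: EllipsoidVOI, grid: ImageVolume) -> BinaryMask:
    """Rasterize the ellipsoid: voxel included iff its center lies inside.

    Inclusion is ``sum(((x - c) / r)^2) <= 1`` at the voxel center.
    """
    coords = [
        np.arange(n) * s for n, s in zip(grid.shape, grid.spacing)
    ]
    terms = []
    for axis, (x, c, r) in enumerate(zip(coords, voi.center, voi.radii)):
        t = ((x - c) / r) ** 2
        shape = [1, 1, 1]
        shape[axis] = -1
        terms.append(t.reshape(shape))
    inside = (terms[0] + terms[1] + terms[2]) <= 1.0
    if not inside.any():
        raise ValueError("ellipsoid VOI contains no voxel center of the grid")
    return BinaryMask(values=inside, spacing=grid.spacing)


def suvmax(pet: ImageVolume, mask: BinaryMask) -> float:
    """Maximum SUV over the masked voxels."""
    check_paired_grid(pet, mask)
    if mask.count() == 0:
        raise ValueError("empty VOI mask")
    return float(pet.values[mask.values].max())


def segment_mtv(
    pet: ImageVolume, mask: BinaryMask, fraction: float = MTV_FRACTION
) -> BinaryMask:
    """VOI voxels with SUV strictly above ``fraction * SUVmax``.

    The comparison is strict, so the segmentation is never empty: the
    maximum voxel always satisfies ``max > fraction * max`` for
    0 < fraction < 1 and positive max.
    """
    if not (0 < fraction < 1):
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    peak = suvmax(pet, mask)
    seg = mask.values & (pet.values > fraction * peak)
    return BinaryMask(values=seg, spacing=mask.spacing)


def tumor_metrics(
    pet: ImageVolume,
    voi: EllipsoidVOI,
    fraction: float = MTV_FRACTION,
    interference: BinaryMask | None = None,
) -> TumorMetrics:
    """SUVmax, MTV and TLG of the lesion enclosed by ``voi``.

    When an interference mask is supplied the PET is cleared inside it
    first, and all metrics (including SUVmax) are taken on the cleared
    volume.
    """
    if interference is not None:
        pet = clear_interference(pet, interference)
    mask = voi_mask(voi, pet)
    peak = suvmax(pet, mask)
    seg = segment_mtv(pet, mask, fraction)
    n = seg.count()
    vox_cm3 = pet.voxel_volume_mm3 / 1000.0
    mtv = n * vox_cm3
    mean_suv = float(pet.values[seg.values].mean())
    return TumorMetrics(
        suvmax=peak,
        mtv=mtv,
        tlg=mtv * mean_suv,
        mtv_mean_suv=mean_suv,
        threshold_fraction=fraction,
    )


def clear_interference(pet: ImageVolume, interference: BinaryMask) -> ImageVolume:
    """Return a copy of the PET with values inside the interference mask zeroed."""
    check_paired_grid(pet, interference)
    values = pet.values.copy()
    values[interference.values] = 0.0
    return ImageVolume(values=values, spacing=pet.spacing, modality=pet.modality)


def gaussian_isocontour_radius_mm(sigma_mm: float, fraction: float = MTV_FRACTION) -> float:
    """Radius where an isotropic Gaussian profile falls to ``fraction`` of its peak."""
    return sigma_mm * np.sqrt(2.0 * np.log(1.0 / fraction))


def gaussian_isocontour_volume_cm3(sigma_mm: float, fraction: float = MTV_FRACTION) -> float:
    """Analytic volume of the ``fraction``-of-peak isocontour of a Gaussian lesion."""
    r = gaussian_isocontour_radius_mm(sigma_mm, fraction)
    return 4.0 / 3.0 * np.pi * r**3 / 1000.0
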