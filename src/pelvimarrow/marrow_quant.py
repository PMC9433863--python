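"""Pelvic active bone marrow quantification from paired CT/PET.

Pelvic bone (BM_TOT) is segmented from CT by thresholding at HU >= 150
inside an operator-supplied pelvic slab (L4-L5 through the ischial
tuberosities in clinical use).  Active marrow (BM_ACT) is the subvolume of
BM_TOT whose SUV is at or above the patient's mean bone SUV; BM_ACT% is
the ratio of the two volumes.  Manual mask correction is represented as an
ordered voxel edit list.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .image_io import BinaryMask, ImageVolume, check_paired_grid

__all__ = [
    "PelvicROI",
    "MaskEdit",
    "BMMetrics",
    "segment_bone",
    "apply_mask_edits",
    "compute_bm_metrics",
    "classify_bm_act_group",
    "read_mask_edits",
]

#: default bone threshold in Hounsfield units (inclusive)
BONE_HU_THRESHOLD = 150.0

#: BM_ACT% group boundaries, percent.  The middle bin is closed on both
#: ends: <30, [30, 40], >40.
BM_GROUP_LOW = 30.0
BM_GROUP_HIGH = 40.0

BM_GROUPS = ("LT30", "MID30_40", "GT40")


@dataclass(frozen=True)
class PelvicROI:
    """Axial slab (plus optional lateral crop) bounding the pelvic bones.

    ``z_lo``/``z_hi`` are inclusive slice indices along the third array
    axis.  ``crop`` optionally restricts the first two axes as
    ``(i_lo, i_hi, j_lo, j_hi)``, also inclusive.
    """

    z_lo: int
    z_hi: int
    crop: tuple[int, int, int, int] | None = None

    def validate(self, shape: tuple[int, int, int]) -> None:
        if not (0 <= self.z_lo <= self.z_hi < shape[2]):
            raise ValueError(f"slab [{self.z_lo}, {self.z_hi}] outside depth {shape[2]}")
        if self.crop is not None:
            i_lo, i_hi, j_lo, j_hi = self.crop
            if not (0 <= i_lo <= i_hi < shape[0] and 0 <= j_lo <= j_hi < shape[1]):
                raise ValueError(f"crop box {self.crop} outside grid {shape[:2]}")

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        self.validate(shape)
        m = np.zeros(shape, dtype=bool)
        if self.crop is None:
            m[:, :, self.z_lo : self.z_hi + 1] = True
        else:
            i_lo, i_hi, j_lo, j_hi = self.crop
            m[i_lo : i_hi + 1, j_lo : j_hi + 1, self.z_lo : self.z_hi + 1] = True
        return m


@dataclass(frozen=True)
class MaskEdit:
    """One manual correction: set voxel ``index`` to true (add) or false (remove)."""

    index: tuple[int, int, int]
    action: str  # "add" | "remove"

    def __post_init__(self) -> None:
        if self.action not in ("add", "remove"):
            raise ValueError(f"action must be 'add' or 'remove', got {self.action!r}")


@dataclass(frozen=True)
class BMMetrics:
    """Bone-marrow volumes and the SUV threshold that defines activity."""

    bm_tot_volume: float  # cm^3
    bm_act_volume: float  # cm^3
    bm_act_pct: float  # percent, (0, 100]
    bone_mean_suv: float

    def __post_init__(self) -> None:
        if not (0 < self.bm_act_volume <= self.bm_tot_volume):
            raise ValueError(
                f"require 0 < BM_ACT ({self.bm_act_volume}) <= BM_TOT ({self.bm_tot_volume})"
            )
        expect = 100.0 * self.bm_act_volume / self.bm_tot_volume
        if abs(self.bm_act_pct - expect) > 1e-9:
            raise ValueError("bm_act_pct inconsistent with volume ratio")


def segment_bone(
    ct: ImageVolume, roi: PelvicROI, hu_threshold: float = BONE_HU_THRESHOLD
) -> BinaryMask:
    """Threshold CT at ``HU >= hu_threshold`` inside the pelvic ROI.

    No morphological cleanup is applied; corrections enter only through
    :func:`apply_mask_edits`.  An empty result raises, since it almost
    always means wrong units or a wrong slab.
    """
    if ct.modality != "CT":
        raise ValueError(f"bone segmentation needs a CT volume, got {ct.modality}")
    mask = (ct.values >= hu_threshold) & roi.mask(ct.shape)
    if not mask.any():
        raise ValueError(
            f"no voxel with HU >= {hu_threshold} inside ROI; check units and slab"
        )
    return BinaryMask(values=mask, spacing=ct.spacing)


def apply_mask_edits(mask: BinaryMask, edits: Sequence[MaskEdit] | Iterable[MaskEdit]) -> BinaryMask:
    """Apply manual corrections in order; the input mask is left untouched."""
    out = mask.values.copy()
    shape = mask.shape
    for e in edits:
        i, j, k = e.index
        if not (0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2]):
            raise IndexError(f"edit index {e.index} outside grid {shape}")
        out[i, j, k] = e.action == "add"
    return BinaryMask(values=out, spacing=mask.spacing)


def read_mask_edits(path: str | os.PathLike) -> list[MaskEdit]:
    """Read an edit list from CSV with columns i,j,k,action."""
    df = pd.read_csv(path)
    return [
        MaskEdit(index=(int(r.i), int(r.j), int(r.k)), action=str(r.action))
        for r in df.itertuples()
    ]


def compute_bm_metrics(pet: ImageVolume, bone_mask: BinaryMask) -> BMMetrics:
    """Compute BM_TOT, BM_ACT and BM_ACT% from the PET over the bone mask.

    The activity threshold is the mean SUV over the (final, corrected) bone
    mask; a voxel counts as active when its SUV is greater than or equal to
    that mean.  Volumes are voxel counts scaled to cm^3.
    """
    if pet.modality != "PET":
        raise ValueError(f"marrow activity needs a PET volume, got {pet.modality}")
    check_paired_grid(pet, bone_mask)
    n_tot = bone_mask.count()
    if n_tot == 0:
        raise ValueError("empty bone mask")
    suv = pet.values[bone_mask.values]
    mean_suv = float(suv.mean())
    n_act = int((suv >= mean_suv).sum())
    vox_cm3 = float(np.prod(bone_mask.spacing)) / 1000.0
    bm_tot = n_tot * vox_cm3
    bm_act = n_act * vox_cm3
    return BMMetrics(
        bm_tot_volume=bm_tot,
        bm_act_volume=bm_act,
        bm_act_pct=100.0 * n_act / n_tot,
        bone_mean_suv=mean_suv,
    )


def classify_bm_act_group(pct: float) -> str:
    """Map BM_ACT% to its group: ``LT30`` (<30), ``MID30_40`` ([30, 40]), ``GT40`` (>40)."""
    if not (0 < pct <= 100):
        raise ValueError(f"BM_ACT% must lie in (0, 100], got {pct}")
    if pct < BM_GROUP_LOW:
        return "LT30"
    if pct <= BM_GROUP_HIGH:
        return "MID30_40"
    return "GT40"
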