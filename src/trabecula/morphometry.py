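"""Whole-vertebra global compactness (GC) and cross-sectional area (CSA).

Both are per-transverse-slice quantities on a binarized whole-vertebra
volume, restricted to slices where the vertebral foramen is completely
surrounded by bone (the closed-foramen rule): a slice qualifies iff its
background has at least one 4-connected component that does not touch
the slice border. Per qualifying slice, bone area is the bone voxel
count times the voxel area and total area is the area of bone plus all
enclosed cavities (2D hole filling, not a convex hull). CSA is the mean
bone area and GC the mean of the per-slice bone/total ratios, both
unweighted means across qualifying slices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import BinaryVolume

__all__ = ["SliceAreas", "MorphometryResult", "slice_inclusion", "gc_csa"]


@dataclass(frozen=True)
class SliceAreas:
    bone_area_mm2: float
    total_area_mm2: float
    foramen_closed: bool

    def __post_init__(self):
        if self.bone_area_mm2 < 0 or self.total_area_mm2 < 0:
            raise ValueError("areas must be nonnegative")
        if self.bone_area_mm2 > self.total_area_mm2 + 1e-12:
            raise ValueError("bone area cannot exceed total area")


@dataclass(frozen=True)
class MorphometryResult:
    csa_mm2: float
    gc: float
    n_slices_included: int

    def __post_init__(self):
        if not (0.0 < self.gc <= 1.0):
            raise ValueError("gc must lie in (0, 1]")
        if self.n_slices_included < 1:
            raise ValueError("at least one slice must be included")


def _has_enclosed_background(slice2d: np.ndarray) -> bool:
    """True iff some 4-connected background component avoids the border."""
    labels, n = ndimage.label(~slice2d)  # 4-connectivity default
    if n == 0:
        return False
    border = np.zeros_like(slice2d)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    touching = np.unique(labels[border & (labels > 0)])
    return n > len(touching)


def slice_inclusion(volume: BinaryVolume) -> np.ndarray:
    """Per-slice closed-foramen flags (axis 2 indexes transverse slices)."""
    flags = np.array(
        [_has_enclosed_background(volume.mask[:, :, k]) for k in range(volume.shape[2])]
    )
    if not flags.any():
        raise ValueError("no enclosed foramen: no slice qualifies")
    return flags


def gc_csa(volume: BinaryVolume, voxel_size_um: float | None = None) -> MorphometryResult:
    """Mean CSA (mm^2) and GC over the closed-foramen slices."""
    if voxel_size_um is None:
        voxel_size_um = volume.voxel_size_um
    flags = slice_inclusion(volume)
    area_per_voxel = (voxel_size_um / 1000.0) ** 2
    bone_areas = []
    ratios = []
    for k in np.nonzero(flags)[0]:
        sl = volume.mask[:, :, k]
        bone = int(sl.sum())
        total = int(ndimage.binary_fill_holes(sl).sum())
        bone_areas.append(bone * area_per_voxel)
        ratios.append(bone / total)
    return MorphometryResult(
        csa_mm2=float(np.mean(bone_areas)),
        gc=float(np.mean(ratios)),
        n_slices_included=int(flags.sum()),
    )


def slice_areas(volume: BinaryVolume) -> list[SliceAreas]:
    """Per-slice areas with the inclusion flag, for reporting."""
    area_per_voxel = (volume.voxel_size_um / 1000.0) ** 2
    out = []
    for k in range(volume.shape[2]):
        sl = volume.mask[:, :, k]
        closed = _has_enclosed_background(sl)
        bone = int(sl.sum()) * area_per_voxel
        total = int(ndimage.binary_fill_holes(sl).sum()) * area_per_voxel
        out.append(SliceAreas(bone, total, closed))
    return out
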