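"""Image-stack I/O, binarization, and volume-of-interest extraction.

Binary volumes are boolean voxel grids with an isotropic physical voxel
size. Axis convention throughout the package:

* axis 0 — dorso-ventral (rows of a transverse slice),
* axis 1 — medio-lateral (columns of a transverse slice),
* axis 2 — cranio-caudal (the slice/stacking axis).

Stacks are stored on disk as multi-page 8-bit TIFF (one page per
transverse slice, 0 = background, 255 = bone) with a JSON sidecar
carrying the voxel size, since plain TIFF has no reliable slot for an
isotropic 3D voxel pitch.

The VOI protocol implemented here mirrors standard practice for
vertebral centra: find the dorsoventrally-then-mediolaterally narrowest
transverse plane of the centrum ("waist"), inscribe the largest
axis-aligned square in the trabecular compartment of that plane, extend
it cranially and caudally while it stays inside the compartment
(a prism), and finally take the largest centered sphere inside the
prism to avoid edge artifacts in the directional metrics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryVolume",
    "PrismVOI",
    "SphereROI",
    "load_stack",
    "save_stack",
    "binarize",
    "default_centrum_mask",
    "extract_prism_voi",
    "inscribed_sphere",
    "sphere_mask",
    "largest_inscribed_square",
]


@dataclass(frozen=True)
class BinaryVolume:
    """A bone/non-bone voxel grid with isotropic physical voxel size."""

    mask: np.ndarray  # 3D bool
    voxel_size_um: float

    def __post_init__(self):
        mask = np.asarray(self.mask)
        if mask.ndim != 3 or mask.size == 0:
            raise ValueError("mask must be a nonempty 3D array")
        if mask.dtype != bool:
            object.__setattr__(self, "mask", mask.astype(bool))
        if not (self.voxel_size_um > 0):
            raise ValueError("voxel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / 1000.0

    def __eq__(self, other):
        if not isinstance(other, BinaryVolume):
            return NotImplemented
        return (
            self.voxel_size_um == other.voxel_size_um
            and self.mask.shape == other.mask.shape
            and bool(np.all(self.mask == other.mask))
        )


@dataclass(frozen=True)
class PrismVOI:
    """Square prism VOI: a square footprint extended along axis 2.

    The footprint covers rows ``row0:row0+side`` and columns
    ``col0:col0+side``; the axial interval ``[z0, z1)`` is half-open.
    """

    side: int
    row0: int
    col0: int
    z0: int
    z1: int

    @property
    def center(self) -> tuple[float, float, float]:
        """Centroid in voxel-index coordinates (voxel i has center i)."""
        half = (self.side - 1) / 2.0
        return (self.row0 + half, self.col0 + half, (self.z0 + self.z1 - 1) / 2.0)

    @property
    def n_slices(self) -> int:
        return self.z1 - self.z0

    def to_json(self) -> str:
        return json.dumps(asdict(self))


@dataclass(frozen=True)
class SphereROI:
    """Sphere in voxel-index coordinates, the analysis region for TBA."""

    center: tuple[float, float, float]
    radius: float

    def to_json(self) -> str:
        return json.dumps({"center": list(self.center), "radius": self.radius})


# ---------------------------------------------------------------------------
# Stack I/O


def save_stack(volume: BinaryVolume, path: str | Path) -> Path:
    """Write a multi-page 8-bit TIFF (pages = transverse slices) + sidecar."""
    path = Path(path)
    pages = (np.moveaxis(volume.mask, 2, 0).astype(np.uint8)) * 255
    tifffile.imwrite(path, pages)
    sidecar = path.with_name(path.name + ".json")
    sidecar.write_text(json.dumps({"voxel_size_um": volume.voxel_size_um}))
    return path


def load_stack(path: str | Path) -> BinaryVolume:
    """Read a binary multi-page TIFF plus its voxel-size sidecar.

    Round-trips :func:`save_stack` bit-exactly. Grayscale stacks (values
    other than {0, 255} or {0, 1}) are rejected with a pointer to
    :func:`binarize`.
    """
    path = Path(path)
    sidecar = path.with_name(path.name + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing sidecar {sidecar.name}: field 'voxel_size_um' is required"
        )
    meta = json.loads(sidecar.read_text())
    if "voxel_size_um" not in meta:
        raise KeyError("sidecar is missing required field 'voxel_size_um'")
    voxel_size = meta["voxel_size_um"]
    if isinstance(voxel_size, (list, tuple)):
        if len(set(voxel_size)) != 1:
            raise ValueError("anisotropic voxel_size_um is not supported")
        voxel_size = voxel_size[0]
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    values = np.unique(pages)
    if not (set(values.tolist()) <= {0, 1, 255}):
        raise ValueError(
            "stack is grayscale, not binary: run binarize() with a threshold first"
        )
    mask = np.moveaxis(pages > 0, 0, 2)
    return BinaryVolume(mask=mask, voxel_size_um=float(voxel_size))


def binarize(
    grayscale: np.ndarray,
    voxel_size_um: float,
    method: str = "fixed",
    threshold: int | None = None,
) -> BinaryVolume:
    """Threshold an 8-bit grayscale stack into a bone mask.

    Bone is ``intensity >= t`` (threshold inclusive, matching the
    127–255 convention of voxel-based TBA software). ``method="otsu"``
    picks ``t`` by between-class variance maximization.
    """
    gray = np.asarray(grayscale)
    if gray.ndim != 3:
        raise ValueError("expected a 3D grayscale stack")
    if method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        t = int(threshold)
    elif method == "otsu":
        if gray.min() == gray.max():
            raise ValueError("otsu thresholding is undefined on a constant image")
        # threshold_otsu returns t with bone > t; shift to the inclusive form
        t = int(threshold_otsu(gray)) + 1
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    mask = gray >= t
    fraction = float(mask.mean())
    logger.info("binarize: threshold=%d bone fraction=%.4f", t, fraction)
    return BinaryVolume(mask=mask, voxel_size_um=voxel_size_um)


# ---------------------------------------------------------------------------
# Centrum mask and prism VOI

_STRUCT_2D_8 = np.ones((3, 3), bool)


def _filled_components(slice2d: np.ndarray):
    """Yield (component mask, hole-filled mask) for each 8-connected bone blob."""
    labels, n = ndimage.label(slice2d, structure=_STRUCT_2D_8)
    for lab in range(1, n + 1):
        comp = labels == lab
        yield comp, ndimage.binary_fill_holes(comp)


def default_centrum_mask(volume: BinaryVolume) -> np.ndarray:
    """Heuristic per-slice centrum mask.

    In each transverse slice, every 8-connected bone component is
    hole-filled; among the filled regions that contain the transverse
    center of the volume, the smallest is taken as the centrum (the
    neural-arch ring, once filled, also covers the center but is always
    larger). Slices where no filled region covers the center are left
    empty. Callers with segmentations of real material should pass
    their own mask to :func:`extract_prism_voi` instead.
    """
    n0, n1, n2 = volume.shape
    center = (n0 // 2, n1 // 2)
    out = np.zeros(volume.shape, bool)
    for k in range(n2):
        best = None
        best_area = None
        for _, filled in _filled_components(volume.mask[:, :, k]):
            if filled[center]:
                area = int(filled.sum())
                if best_area is None or area < best_area:
                    best, best_area = filled, area
        if best is not None:
            out[:, :, k] = best
    return out


def largest_inscribed_square(region: np.ndarray) -> tuple[int, int, int]:
    """Largest axis-aligned all-True square in a 2D mask.

    Returns ``(side, row0, col0)`` of the top-left corner. Among
    maximal squares the one whose center is nearest the region centroid
    wins; remaining ties go to the smallest (row0, col0). Dynamic
    programming over bottom-right corners, O(rows x cols).
    """
    reg = np.asarray(region, bool)
    if not reg.any():
        return 0, 0, 0
    n0, n1 = reg.shape
    size = np.zeros((n0, n1), np.int32)
    size[0, :] = reg[0, :]
    size[:, 0] = reg[:, 0]
    for i in range(1, n0):
        prev = size[i - 1]
        cur = size[i]
        row = reg[i]
        # size[i, j] = min(size[i-1, j], size[i, j-1], size[i-1, j-1]) + 1
        for j in range(1, n1):
            if row[j]:
                cur[j] = min(prev[j], cur[j - 1], prev[j - 1]) + 1
    side = int(size.max())
    rows, cols = np.nonzero(size == side)
    cy, cx = ndimage.center_of_mass(reg)
    half = (side - 1) / 2.0
    centers_r = rows - side + 1 + half
    centers_c = cols - side + 1 + half
    d2 = (centers_r - cy) ** 2 + (centers_c - cx) ** 2
    order = np.lexsort((cols, rows, d2))
    best = order[0]
    return side, int(rows[best] - side + 1), int(cols[best] - side + 1)


def _interior_region(bone2d: np.ndarray, centrum2d: np.ndarray) -> np.ndarray:
    """Trabecular compartment of one slice: the part of the centrum
    interior to the cortical shell.

    The shell thickness is read off the slice itself: pore pixels can
    only occur inward of the cortex, so every centrum pixel at least as
    deep (Euclidean distance from the centrum boundary) as the
    shallowest pore belongs to the compartment. Trabecular bone inside
    the shell is included; a slice with no pores has no compartment.
    """
    pores = centrum2d & ~bone2d
    if not pores.any():
        return np.zeros_like(pores)
    depth = ndimage.distance_transform_edt(centrum2d)
    shell = depth[pores].min()
    return centrum2d & (depth >= shell)


def extract_prism_voi(
    volume: BinaryVolume,
    centrum_mask: np.ndarray | None = None,
) -> PrismVOI:
    """Prism VOI at the centrum waist.

    The waist is the transverse slice minimizing (dorso-ventral extent,
    then medio-lateral extent) of the centrum; exact ties go to the
    slice nearest the axial midpoint. The prism footprint is the
    largest axis-aligned square inscribed in the trabecular compartment
    of the waist slice, and the axial interval grows cranially and
    caudally for as long as every added slice's compartment still
    contains the footprint.
    """
    if centrum_mask is None:
        centrum_mask = default_centrum_mask(volume)
    centrum_mask = np.asarray(centrum_mask, bool)
    if centrum_mask.shape != volume.shape:
        raise ValueError("centrum mask shape must match volume shape")

    n2 = volume.shape[2]
    candidates = [k for k in range(n2) if centrum_mask[:, :, k].any()]
    if not candidates:
        raise ValueError("VOI too small: empty centrum mask")

    def extents(k: int) -> tuple[int, int]:
        sl = centrum_mask[:, :, k]
        r = np.nonzero(sl.any(axis=1))[0]
        c = np.nonzero(sl.any(axis=0))[0]
        return int(r[-1] - r[0] + 1), int(c[-1] - c[0] + 1)

    mid = (n2 - 1) / 2.0
    waist = min(candidates, key=lambda k: (*extents(k), abs(k - mid), k))

    interior = _interior_region(volume.mask[:, :, waist], centrum_mask[:, :, waist])
    side, row0, col0 = largest_inscribed_square(interior)
    if side < 3:
        raise ValueError("VOI too small: trabecular interior under 3 voxels across")

    def fits(k: int) -> bool:
        if k not in candidates:
            return False
        reg = _interior_region(volume.mask[:, :, k], centrum_mask[:, :, k])
        return bool(reg[row0 : row0 + side, col0 : col0 + side].all())

    z0 = waist
    while z0 - 1 >= 0 and fits(z0 - 1):
        z0 -= 1
    z1 = waist + 1
    while z1 < n2 and fits(z1):
        z1 += 1
    return PrismVOI(side=side, row0=row0, col0=col0, z0=z0, z1=z1)


def inscribed_sphere(voi: PrismVOI) -> SphereROI:
    """Largest centered sphere inside the prism: radius = min(side, depth)/2."""
    radius = min(voi.side, voi.n_slices) / 2.0
    return SphereROI(center=voi.center, radius=radius)


def sphere_mask(shape: tuple[int, int, int], roi: SphereROI) -> np.ndarray:
    """Boolean mask of voxels whose centers fall inside the sphere."""
    c0, c1, c2 = roi.center
    i0 = np.arange(shape[0], dtype=float)[:, None, None]
    i1 = np.arange(shape[1], dtype=float)[None, :, None]
    i2 = np.arange(shape[2], dtype=float)[None, None, :]
    d2 = (i0 - c0) ** 2 + (i1 - c1) ** 2 + (i2 - c2) ** 2
    return d2 <= roi.radius**2
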