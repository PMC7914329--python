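"""Core domain types and geometric utilities.

Coordinate convention (used everywhere in the package): voxel indices are
0-based, a voxel index refers to the voxel *center*, and world coordinates
are ``world = origin + index * spacing`` (axis-aligned grids; no oblique
orientations).  All images are 3-D scalar grids of SUV (standardized uptake
value, dimensionless) and all masks are binary grids aligned voxel-for-voxel
with their image.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage


class PetradError(Exception):
    """Base class for all package errors."""


class AlignmentError(PetradError):
    """Image and mask grids do not share shape/spacing/origin."""


class EmptyVOIError(PetradError):
    """An operation that requires a non-empty VOI received an empty mask."""


class DegenerateLesionError(PetradError):
    """A synthetic lesion was requested below the resolvable size."""


class EmptyResultError(PetradError):
    """A segmentation converged to the empty set (no separable lesion)."""


def _as_triple(x) -> tuple[float, float, float]:
    a = np.broadcast_to(np.asarray(x, dtype=float), (3,))
    return (float(a[0]), float(a[1]), float(a[2]))


@dataclass
class SUVImage:
    """A 3-D PET image in SUV units on a regular axis-aligned grid.

    Parameters
    ----------
    values : (nx, ny, nz) float array
        SUV values; must be finite and non-negative.
    spacing : 3-tuple of float
        Voxel edge lengths in mm, strictly positive.
    origin : 3-tuple of float
        World position (mm) of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"SUVImage must be 3-D, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SUV values must be finite")
        if np.any(self.values < 0):
            raise ValueError("SUV values must be >= 0")
        self.spacing = _as_triple(self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = _as_triple(self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class VOIMask:
    """A binary volume of interest on the same grid as its paired SUVImage."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError(f"VOIMask must be 3-D, got ndim={self.values.ndim}")
        self.spacing = _as_triple(self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = _as_triple(self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def volume_ml(self) -> float:
        return self.voxel_count() * self.voxel_volume_mm3 / 1000.0

    def with_label(self, label: str) -> "VOIMask":
        return replace(self, label=label)


@dataclass
class LesionRecord:
    """One lesion: its image crop, ground-truth mask (synthetic cohorts only)
    and any number of delineations (operators, level set, consensus...)."""

    lesion_id: str
    patient_id: str
    image: SUVImage
    truth: VOIMask | None = None
    delineations: list[VOIMask] = field(default_factory=list)

    def __post_init__(self):
        for m in ([self.truth] if self.truth is not None else []) + list(self.delineations):
            check_aligned(self.image, m)

    def delineation(self, label: str) -> VOIMask:
        for m in self.delineations:
            if m.label == label:
                return m
        raise KeyError(f"no delineation labelled {label!r} on lesion {self.lesion_id}")


def check_aligned(image: SUVImage, mask: VOIMask) -> None:
    """Raise :class:`AlignmentError` unless mask and image share one grid."""
    if image.shape != mask.shape:
        raise AlignmentError(f"shape mismatch: image {image.shape} vs mask {mask.shape}")
    if not np.allclose(image.spacing, mask.spacing):
        raise AlignmentError(f"spacing mismatch: {image.spacing} vs {mask.spacing}")
    if not np.allclose(image.origin, mask.origin):
        raise AlignmentError(f"origin mismatch: {image.origin} vs {mask.origin}")


# ---------------------------------------------------------------------------
# resampling / cropping
# ---------------------------------------------------------------------------

def resample_isotropic(
    image: SUVImage, mask: VOIMask, target_spacing_mm: float
) -> tuple[SUVImage, VOIMask]:
    """Resample an image/mask pair to an isotropic grid.

    The image is interpolated trilinearly and the mask by nearest neighbour,
    so mask labels never take partial-volume values.  The output grid keeps
    the input origin and covers only voxel centers lying inside the input
    domain (no extrapolation).  If the input is already at the target spacing
    on all axes the inputs are returned unchanged (bit-for-bit).
    """
    if target_spacing_mm <= 0:
        raise ValueError("target_spacing_mm must be > 0")
    check_aligned(image, mask)
    spacing = np.asarray(image.spacing)
    if np.allclose(spacing, target_spacing_mm):
        return image, mask

    shape = np.asarray(image.shape)
    # largest n' with (n'-1) * s' <= (n-1) * s  -> sample points stay in-domain
    new_shape = np.floor((shape - 1) * spacing / target_spacing_mm).astype(int) + 1
    new_shape = np.maximum(new_shape, 1)
    # old fractional index of each new voxel center
    grids = [
        np.arange(n) * target_spacing_mm / spacing[ax]
        for ax, n in enumerate(new_shape)
    ]
    coords = np.meshgrid(*grids, indexing="ij")
    new_vals = ndimage.map_coordinates(image.values, coords, order=1, mode="nearest")
    near = [np.clip(np.round(g).astype(int), 0, s - 1) for g, s in zip(grids, shape)]
    ncoords = np.meshgrid(*near, indexing="ij")
    new_mask = mask.values[tuple(ncoords)]
    t = (target_spacing_mm,) * 3
    return (
        SUVImage(np.clip(new_vals, 0.0, None), t, image.origin),
        VOIMask(new_mask, t, mask.origin, label=mask.label),
    )


def crop_to_mask(
    image: SUVImage, mask: VOIMask, margin_voxels: int = 0
) -> tuple[SUVImage, VOIMask]:
    """Crop image and mask to the mask's bounding box plus a voxel margin.

    The margin is clipped at the image border; in-mask SUV values are
    preserved exactly.  Feature extraction is invariant under this crop.
    """
    check_aligned(image, mask)
    if mask.voxel_count() == 0:
        raise EmptyVOIError("cannot crop to an empty mask")
    if margin_voxels < 0:
        raise ValueError("margin_voxels must be >= 0")
    idx = np.nonzero(mask.values)
    lo = [max(0, int(a.min()) - margin_voxels) for a in idx]
    hi = [min(s, int(a.max()) + 1 + margin_voxels) for a, s in zip(idx, mask.shape)]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    new_origin = tuple(
        o + a * s for o, a, s in zip(image.origin, lo, image.spacing)
    )
    return (
        SUVImage(image.values[sl].copy(), image.spacing, new_origin),
        VOIMask(mask.values[sl].copy(), mask.spacing, new_origin, label=mask.label),
    )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def read_suv_image(path) -> SUVImage:
    """Read a NIfTI volume as an SUVImage (axis-aligned affines only)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return SUVImage(np.clip(data, 0.0, None), spacing, origin)


def write_suv_image(image: SUVImage, path) -> None:
    nib.save(nib.Nifti1Image(image.values, _affine(image.spacing, image.origin)), str(path))


def read_voi_mask(path, label: str = "") -> VOIMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return VOIMask(data > 0.5, spacing, origin, label=label)


def write_voi_mask(mask: VOIMask, path) -> None:
    arr = mask.values.astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, _affine(mask.spacing, mask.origin)), str(path))


def read_seed_points(path) -> dict[str, tuple[int, int, int]]:
    """Read a plain-text seed file: one ``lesion_id x y z`` (voxel indices)
    per line; blank lines and ``#`` comments ignored."""
    seeds: dict[str, tuple[int, int, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"malformed seed line: {line!r}")
            seeds[parts[0]] = (int(parts[1]), int(parts[2]), int(parts[3]))
    return seeds
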