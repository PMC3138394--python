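"""Registration volumes: binary masks, isotropic mm margins, centers of mass.

The registration volume hierarchy used throughout the package is the
delineated prostate gland (``RV0``) and its isotropic 3D margin expansions
(``RV1``/``RV2``/``RV3`` for 1/2/3 cm by default), plus the trivial
full-grid mask used for whole-pelvis registration.  Margins are isotropic
in *world* millimetres, not in voxels: on an anisotropic grid (e.g.
1.17 x 1.17 x 1.7 mm) the expansion radius must not depend on direction,
so it is computed with a spacing-aware Euclidean distance transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import EmptyMaskError, GeometryError
from .geometry import AXIS_LABELS, ImageVolume, _as_vec3

#: Canonical ordering of registration volumes, smallest first.  Also the
#: tie-break priority when two volumes achieve the same precision.
VOLUME_ORDER = ("RV0", "RV1", "RV2", "RV3", "full")


@dataclass
class BinaryMask:
    """A boolean grid sharing an :class:`~subvolreg.geometry.ImageVolume` geometry."""

    grid: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray
    axis_labels: tuple = AXIS_LABELS

    def __post_init__(self):
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.ndim != 3:
            raise ValueError(f"mask grid must be 3D, got ndim={self.grid.ndim}")
        self.spacing_mm = _as_vec3(self.spacing_mm, "spacing_mm")
        if np.any(self.spacing_mm <= 0):
            raise ValueError("spacing_mm must be strictly positive per axis")
        self.origin_mm = _as_vec3(self.origin_mm, "origin_mm")
        self.axis_labels = tuple(self.axis_labels)

    @property
    def shape(self) -> tuple:
        return self.grid.shape

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())

    def is_empty(self) -> bool:
        return not bool(self.grid.any())

    def same_geometry(self, other, tol: float = 1e-6) -> bool:
        """Geometric consistency with another mask or :class:`ImageVolume`."""
        return (
            self.shape == tuple(np.shape(other_grid(other)))
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=tol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=tol)
        )

    def require_same_geometry(self, other, what: str = "mask and volume"):
        if not self.same_geometry(other):
            raise GeometryError(f"{what} do not share grid geometry")

    def indices(self) -> np.ndarray:
        """(N, 3) integer indices of true voxels, in C order."""
        return np.argwhere(self.grid)

    def world_points(self) -> np.ndarray:
        """(N, 3) world coordinates (mm) of true voxel centers."""
        return self.origin_mm + self.indices() * self.spacing_mm

    def copy(self) -> "BinaryMask":
        return BinaryMask(
            self.grid.copy(), self.spacing_mm.copy(), self.origin_mm.copy(), self.axis_labels
        )


def other_grid(obj):
    """Boolean/scalar grid of a mask or volume, for geometry comparison."""
    return obj.grid if isinstance(obj, BinaryMask) else obj.data


def expand_mask(mask: BinaryMask, margin_mm: float) -> BinaryMask:
    """Expand a mask by an isotropic margin in world millimetres.

    An output voxel is true iff its Euclidean distance (computed with the
    per-axis voxel spacing) to the nearest true input voxel is at most
    ``margin_mm``.  The expansion is clipped at the grid extent: margins
    that reach past the field of view are silently truncated there.

    Raises
    ------
    EmptyMaskError
        If the input delineation is empty.
    ValueError
        If ``margin_mm`` is negative.
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")
    if mask.is_empty():
        raise EmptyMaskError("empty delineation")
    if margin_mm == 0:
        return mask.copy()
    # distance of every voxel to the nearest true voxel, in mm
    dist = ndimage.distance_transform_edt(~mask.grid, sampling=mask.spacing_mm)
    return BinaryMask(dist <= margin_mm, mask.spacing_mm, mask.origin_mm, mask.axis_labels)


def full_volume_mask(volume: ImageVolume) -> BinaryMask:
    """Mask covering every voxel of a volume's grid (whole-pelvis registration)."""
    return BinaryMask(
        np.ones(volume.shape, dtype=bool),
        volume.spacing_mm,
        volume.origin_mm,
        volume.axis_labels,
    )


def mask_center_of_mass(mask: BinaryMask) -> np.ndarray:
    """Unweighted mean world coordinate (mm) of the true voxels.

    Raises
    ------
    EmptyMaskError
        If the mask has no true voxel.
    """
    if mask.is_empty():
        raise EmptyMaskError("empty delineation")
    idx_mean = ndimage.center_of_mass(mask.grid)
    return mask.origin_mm + np.asarray(idx_mean) * mask.spacing_mm


def mask_from_volume(volume: ImageVolume, grid: np.ndarray) -> BinaryMask:
    """Wrap a boolean array in the geometry of an existing volume."""
    grid = np.asarray(grid).astype(bool)
    if grid.shape != volume.shape:
        raise GeometryError("boolean grid shape does not match volume shape")
    return BinaryMask(grid, volume.spacing_mm, volume.origin_mm, volume.axis_labels)
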