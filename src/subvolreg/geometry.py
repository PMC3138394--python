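"""Geometric primitives: scalar image volumes and versor rigid transforms.

The package works in a fixed anatomical world frame, in millimetres:

* ``x`` — right-left (RL)
* ``y`` — anterior-posterior (AP)
* ``z`` — cranio-caudal (CC)

Array index ``(i, j, k)`` maps to world space through
``world = origin_mm + index * spacing_mm``; voxel *centers* carry the
coordinates and indices are 0-based.  All internal grids are axis-aligned;
oblique acquisitions are reoriented on load (see :mod:`subvolreg.io`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import GeometryError

#: Anatomical meaning of array axes 0, 1, 2 (and world x, y, z).
AXIS_LABELS = ("RL", "AP", "CC")

_GEOM_TOL = 1e-6


def _as_vec3(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float).reshape(-1)
    if a.size != 3:
        raise ValueError(f"{name} must have 3 components, got {a.size}")
    return a


@dataclass
class ImageVolume:
    """A 3D scalar grid with voxel spacing and world origin.

    Parameters
    ----------
    data
        3D array of intensities (stored as float64).
    spacing_mm
        Per-axis voxel size in mm, strictly positive.
    origin_mm
        World coordinate of voxel ``(0, 0, 0)``.
    axis_labels
        Anatomical direction of each array axis; the default and only
        supported internal convention is ``("RL", "AP", "CC")``.
    """

    data: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray
    axis_labels: tuple = AXIS_LABELS

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3D, got ndim={self.data.ndim}")
        self.spacing_mm = _as_vec3(self.spacing_mm, "spacing_mm")
        if np.any(self.spacing_mm <= 0):
            raise ValueError("spacing_mm must be strictly positive per axis")
        self.origin_mm = _as_vec3(self.origin_mm, "origin_mm")
        self.axis_labels = tuple(self.axis_labels)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one array axis."""
        n = self.data.shape[axis]
        return self.origin_mm[axis] + self.spacing_mm[axis] * np.arange(n)

    def index_to_world(self, index) -> np.ndarray:
        """Map (possibly fractional) voxel indices to world mm coordinates."""
        idx = np.asarray(index, dtype=float)
        return self.origin_mm + idx * self.spacing_mm

    def world_extent(self) -> np.ndarray:
        """(2, 3) array of [min, max] voxel-center coordinates per axis."""
        hi = self.origin_mm + (np.array(self.shape) - 1) * self.spacing_mm
        return np.stack([self.origin_mm, hi])

    def same_geometry(self, other, tol: float = _GEOM_TOL) -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=tol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=tol)
            and self.axis_labels == tuple(other.axis_labels)
        )

    def require_same_geometry(self, other, what: str = "volumes"):
        if not self.same_geometry(other):
            raise GeometryError(f"{what} do not share grid geometry")

    def copy(self) -> "ImageVolume":
        return ImageVolume(
            self.data.copy(), self.spacing_mm.copy(), self.origin_mm.copy(), self.axis_labels
        )


def centered_origin(shape, spacing_mm) -> np.ndarray:
    """Origin placing the world origin at the grid center (symmetric FOV)."""
    shape = np.asarray(shape, dtype=float)
    spacing = _as_vec3(spacing_mm, "spacing_mm")
    return -(shape - 1) * spacing / 2.0


@dataclass(frozen=True)
class RigidTransform:
    """Rigid 3D map ``p' = R(versor) @ (p - center) + center + translation``.

    The rotation is a versor (unit quaternion) stored in scalar-last order
    ``(x, y, z, w)`` with ``w >= 0``; its vector part supplies the three
    rotation parameters optimized during registration, the other three being
    the translation components.  ``center_mm`` is held fixed during
    optimization.
    """

    versor: np.ndarray
    translation_mm: np.ndarray
    center_mm: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.versor, dtype=float).reshape(-1)
        if q.size != 4:
            raise ValueError("versor must have 4 components (x, y, z, w)")
        n = float(np.linalg.norm(q))
        if abs(n - 1.0) > 1e-6:
            raise ValueError(f"versor norm {n} is not 1 within 1e-6")
        q = q / n
        if q[3] < 0:
            q = -q
        object.__setattr__(self, "versor", q)
        object.__setattr__(self, "translation_mm", _as_vec3(self.translation_mm, "translation_mm"))
        object.__setattr__(self, "center_mm", _as_vec3(self.center_mm, "center_mm"))

    # ------------------------------------------------------------------ #
    # constructors
    # ------------------------------------------------------------------ #
    @classmethod
    def identity(cls, center_mm=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(np.array([0.0, 0.0, 0.0, 1.0]), np.zeros(3), center_mm)

    @classmethod
    def from_params(cls, params, center_mm) -> "RigidTransform":
        """Build from the 6 optimizer parameters (vx, vy, vz, tx, ty, tz).

        The versor scalar part is reconstructed as ``w = sqrt(1 - |v|^2)``,
        so the parameter vector must satisfy ``|v| < 1``.
        """
        p = np.asarray(params, dtype=float).reshape(-1)
        if p.size != 6:
            raise ValueError("params must have 6 components")
        v = p[:3]
        n2 = float(v @ v)
        if n2 >= 1.0:
            raise ValueError("versor vector part must have norm < 1")
        w = np.sqrt(1.0 - n2)
        return cls(np.array([v[0], v[1], v[2], w]), p[3:], center_mm)

    @classmethod
    def from_rotvec_deg(cls, rotvec_deg, translation_mm, center_mm) -> "RigidTransform":
        """Build from a rotation vector in degrees (axis * angle)."""
        rot = Rotation.from_rotvec(np.asarray(rotvec_deg, dtype=float), degrees=True)
        return cls(rot.as_quat(), translation_mm, center_mm)

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, center_mm=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Build from a 4x4 homogeneous rigid matrix, with a chosen center."""
        M = np.asarray(matrix, dtype=float)
        R = M[:3, :3]
        b = M[:3, 3]
        c = _as_vec3(center_mm, "center_mm")
        q = Rotation.from_matrix(R).as_quat()
        # b = c + t - R c  =>  t = b - c + R c
        t = b - c + R @ c
        return cls(q, t, c)

    # ------------------------------------------------------------------ #
    # views
    # ------------------------------------------------------------------ #
    @property
    def params(self) -> np.ndarray:
        """The 6 optimizer parameters (versor vector part, translation)."""
        return np.concatenate([self.versor[:3], self.translation_mm])

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.versor)

    @property
    def rotation_matrix(self) -> np.ndarray:
        return self.rotation.as_matrix()

    @property
    def rotation_angle_deg(self) -> float:
        return float(np.degrees(self.rotation.magnitude()))

    def matrix(self) -> np.ndarray:
        """Equivalent 4x4 homogeneous matrix."""
        R = self.rotation_matrix
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = self.center_mm + self.translation_mm - R @ self.center_mm
        return M

    # ------------------------------------------------------------------ #
    # actions
    # ------------------------------------------------------------------ #
    def apply(self, points_mm) -> np.ndarray:
        """Transform one point (3,) or many (N, 3)."""
        p = np.asarray(points_mm, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        out = (p - self.center_mm) @ self.rotation_matrix.T + self.center_mm + self.translation_mm
        return out[0] if single else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first), centered at self's center."""
        return RigidTransform.from_matrix(self.matrix() @ other.matrix(), self.center_mm)

    def inverse(self) -> "RigidTransform":
        """Inverse map, sharing the same rotation center."""
        R = self.rotation_matrix
        return RigidTransform(
            Rotation.from_matrix(R.T).as_quat(), -(R.T @ self.translation_mm), self.center_mm
        )

    def with_center(self, center_mm) -> "RigidTransform":
        """Same mapping expressed about a different rotation center."""
        return RigidTransform.from_matrix(self.matrix(), center_mm)

    def to_dict(self) -> dict:
        return {
            "versor": self.versor.tolist(),
            "translation_mm": self.translation_mm.tolist(),
            "center_mm": self.center_mm.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["versor"]), d["translation_mm"], d["center_mm"])


def transform_point(transform: RigidTransform, point_mm) -> np.ndarray:
    """Functional alias for :meth:`RigidTransform.apply`."""
    return transform.apply(point_mm)
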