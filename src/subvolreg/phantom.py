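"""Synthetic repeat-MR pelvic phantom with known rigid prostate motion.

The generator emulates the geometry of a T2-weighted 3D pelvic acquisition
(axial slices, 384 x 348 matrix, 120 slices, 1.17 x 1.17 mm in-plane,
1.7 mm slice thickness) repeated several times over a course of treatment.
Each patient series shares a static skeleton — body outline, pelvic bone
shells and a fixed soft-tissue texture — while

* the prostate (an ellipsoid with internal intensity structure) is
  displaced *rigidly* between series, dominantly in the anterior-posterior
  direction, by a draw from a configurable zero-mean motion distribution;
* rectum and bladder change size and content intensity between series,
  mimicking variable filling; and
* independent Rician (MR-magnitude) noise is applied to every series.

Because the prostate motion is applied analytically, the ground-truth
rigid transform of every series is known exactly, as is the transported
prostate delineation, which makes every downstream registration and
precision statistic verifiable without real data.

All anatomy is analytic geometry rasterized with ~1-voxel anti-aliased
edges; nothing is downloaded or stored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import FieldOfViewError
from .geometry import ImageVolume, RigidTransform, centered_origin
from .masks import BinaryMask

# ---------------------------------------------------------------------- #
# grids
# ---------------------------------------------------------------------- #

#: Acquisition-matched grid: matrix 384 x 348, 120 slices.
GRID_ACQUISITION = {"grid_shape": (384, 348, 120), "spacing_mm": (1.17, 1.17, 1.7)}

#: Desk-scale grid preserving the acquisition field of view
#: (449.3 x 407.2 x 204.0 mm) at coarser spacing.
GRID_SMALL = {
    "grid_shape": (96, 96, 60),
    "spacing_mm": (384 * 1.17 / 96, 348 * 1.17 / 96, 120 * 1.7 / 60),
}

# T2-like intensity palette (arbitrary units, 0 = air)
_I_TISSUE = 35.0
_I_CORTICAL = 8.0
_I_MARROW = 60.0
_I_PROSTATE = 55.0
_I_BLADDER = 88.0


@dataclass
class PhantomConfig:
    """Study conditions for one synthetic patient.

    Defaults model the motion anisotropy of the prostate relative to the
    bony anatomy (largest anterior-posterior, smallest right-left) and a
    moderate inter-series change in rectum/bladder appearance.
    """

    grid_shape: Sequence[int] = GRID_SMALL["grid_shape"]
    spacing_mm: Sequence[float] = GRID_SMALL["spacing_mm"]
    n_series: int = 4
    #: per-axis SD of the prostate displacement (RL, AP, CC), mm
    prostate_motion_sd_mm: Sequence[float] = (0.5, 4.0, 2.5)
    #: SD of the prostate rotation angle per axis, degrees
    prostate_rotation_sd_deg: float = 1.0
    #: dimensionless amplitude of rectum/bladder appearance change (0 = frozen)
    organ_variation_scale: float = 1.0
    #: Rician noise scale, intensity units (tissue contrast spans ~0-90)
    noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if len(self.grid_shape) != 3 or any(n < 8 for n in self.grid_shape):
            raise ValueError("grid_shape must be 3 axes of at least 8 voxels")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive per axis")
        if self.n_series < 2:
            raise ValueError("n_series must be >= 2")
        if any(s < 0 for s in self.prostate_motion_sd_mm):
            raise ValueError("motion SDs must be >= 0")
        if self.prostate_rotation_sd_deg < 0 or self.noise_sigma < 0:
            raise ValueError("SDs must be >= 0")
        if self.organ_variation_scale < 0:
            raise ValueError("organ_variation_scale must be >= 0")

    @property
    def origin_mm(self) -> np.ndarray:
        return centered_origin(self.grid_shape, self.spacing_mm)


@dataclass
class PatientSeries:
    """All repeat series of one synthetic patient, with ground truth."""

    volumes: List[ImageVolume]
    prostate_masks: List[BinaryMask]
    #: rigid map taking reference-series prostate points to series-k points;
    #: index 0 is the identity.  Empty list for externally loaded data.
    true_prostate_transforms: List[RigidTransform]
    patient_id: str

    @property
    def n_series(self) -> int:
        return len(self.volumes)

    @property
    def reference(self) -> ImageVolume:
        return self.volumes[0]


# ---------------------------------------------------------------------- #
# analytic shapes (alpha in [0, 1], anti-aliased over ``edge_mm``)
# ---------------------------------------------------------------------- #


def _ellipsoid_alpha(X, Y, Z, center, semi_axes, edge_mm):
    a, b, c = semi_axes
    rho = np.sqrt(
        ((X - center[0]) / a) ** 2 + ((Y - center[1]) / b) ** 2 + ((Z - center[2]) / c) ** 2
    )
    d = (rho - 1.0) * min(semi_axes)  # approximate signed distance, mm
    return np.clip(0.5 - d / edge_mm, 0.0, 1.0)


def _superellipse_alpha(X, Y, center, semi_axes, edge_mm, power=4):
    a, b = semi_axes
    rho = (np.abs((X - center[0]) / a) ** power + np.abs((Y - center[1]) / b) ** power) ** (
        1.0 / power
    )
    d = (rho - 1.0) * min(semi_axes)
    return np.clip(0.5 - d / edge_mm, 0.0, 1.0)


def _tube_alpha(X, Y, center_xy, radius, edge_mm):
    d = np.sqrt((X - center_xy[0]) ** 2 + (Y - center_xy[1]) ** 2) - radius
    return np.clip(0.5 - d / edge_mm, 0.0, 1.0)


def _paint(canvas, alpha, intensity):
    np.multiply(canvas, 1.0 - alpha, out=canvas)
    canvas += alpha * intensity
    return canvas


# ---------------------------------------------------------------------- #
# noise
# ---------------------------------------------------------------------- #


def apply_noise(volume: ImageVolume, sigma: float, seed: int) -> ImageVolume:
    """Add MR-magnitude (Rician) noise to a volume.

    Each output voxel is ``|signal + n1 + i*n2|`` with ``n1, n2`` i.i.d.
    Gaussian of scale ``sigma``; for zero signal this reduces to a Rayleigh
    background of mean ``sigma * sqrt(pi/2)``.  ``sigma = 0`` returns an
    unchanged copy.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return volume.copy()
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=volume.shape)
    n2 = rng.normal(0.0, sigma, size=volume.shape)
    data = np.hypot(volume.data + n1, n2)
    return ImageVolume(data, volume.spacing_mm, volume.origin_mm, volume.axis_labels)


# ---------------------------------------------------------------------- #
# patient generation
# ---------------------------------------------------------------------- #


def _seed_int(*entropy) -> int:
    """Deterministic 31-bit integer seed from a tuple of integers."""
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


class _Anatomy:
    """Per-patient morphology drawn once, shared by every series."""

    def __init__(self, config: PhantomConfig, rng: np.random.Generator):
        u = rng.uniform
        self.body_semi = np.array([165.0 * u(0.95, 1.05), 105.0 * u(0.95, 1.05)])
        self.prostate_center = np.array([0.0, u(-4.0, 4.0), u(-6.0, 6.0)])
        self.prostate_semi = np.array([20.0, 17.0, 19.0]) * u(0.9, 1.1, size=3)
        # internal zonal-like intensity structure, fixed in the prostate frame
        self.blob_offsets = rng.uniform(-0.5, 0.5, size=(3, 3)) * self.prostate_semi
        self.blob_amplitude = rng.uniform(12.0, 20.0, size=3) * rng.choice([-1.0, 1.0], size=3)
        self.blob_sigma = rng.uniform(5.0, 8.0, size=3)
        self.bladder_center = self.prostate_center + np.array([0.0, -32.0, 42.0])
        self.bladder_radius = 28.0 * u(0.9, 1.1)
        self.rectum_center_xy = self.prostate_center[:2] + np.array([0.0, 40.0])
        self.rectum_radius = 14.0 * u(0.9, 1.1)
        self.femoral_x = 88.0 * u(0.95, 1.05)
        # static soft-tissue texture parameters
        self.texture_seed = int(rng.integers(0, 2**31))


def _static_background(config: PhantomConfig, anat: _Anatomy, X, Y, Z, edge):
    """Body, bones and static texture: identical for every series of a patient."""
    vol = np.zeros(config.grid_shape, dtype=float)
    body = _superellipse_alpha(X, Y, (0.0, 0.0), anat.body_semi, edge)
    _paint(vol, body, _I_TISSUE)

    # static smooth soft-tissue texture confined to the body
    trng = np.random.default_rng(anat.texture_seed)
    tex = trng.normal(0.0, 1.0, size=config.grid_shape)
    tex = ndimage.gaussian_filter(tex, sigma=2.5)
    tex *= 10.0 / max(tex.std(), 1e-12)
    vol += body * tex

    # femoral heads: dark cortical shell around bright marrow
    for sx in (-1.0, 1.0):
        c = (sx * anat.femoral_x, 0.0, 0.0)
        cort = _ellipsoid_alpha(X, Y, Z, c, (24.0, 24.0, 34.0), edge)
        _paint(vol, cort, _I_CORTICAL)
        marr = _ellipsoid_alpha(X, Y, Z, c, (18.0, 18.0, 28.0), edge)
        _paint(vol, marr, _I_MARROW)
    # sacrum block, posterior midline
    cort = _ellipsoid_alpha(X, Y, Z, (0.0, 78.0, 10.0), (34.0, 20.0, 55.0), edge)
    _paint(vol, cort, _I_CORTICAL)
    marr = _ellipsoid_alpha(X, Y, Z, (0.0, 78.0, 10.0), (26.0, 14.0, 47.0), edge)
    _paint(vol, marr, _I_MARROW)
    return vol


def _prostate_fields(anat: _Anatomy, P, edge):
    """Alpha and textured intensity of the prostate at points P (prostate frame)."""
    X, Y, Z = P
    alpha = _ellipsoid_alpha(X, Y, Z, anat.prostate_center, anat.prostate_semi, edge)
    intensity = np.full_like(alpha, _I_PROSTATE)
    for off, amp, sig in zip(anat.blob_offsets, anat.blob_amplitude, anat.blob_sigma):
        c = anat.prostate_center + off
        r2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
        intensity += amp * np.exp(-0.5 * r2 / sig**2)
    return alpha, intensity


def _draw_motion(config: PhantomConfig, rng: np.random.Generator, center) -> RigidTransform:
    t = rng.normal(0.0, config.prostate_motion_sd_mm, size=3)
    rotvec = rng.normal(0.0, config.prostate_rotation_sd_deg, size=3)
    return RigidTransform.from_rotvec_deg(rotvec, t, center)


def _check_fov(config: PhantomConfig, anat: _Anatomy, transform: RigidTransform):
    new_center = transform.apply(anat.prostate_center)
    half_fov = -config.origin_mm  # symmetric, centered grid
    reach = max(anat.prostate_semi) + 2.0 * max(config.spacing_mm)
    if np.any(np.abs(new_center) + reach > half_fov):
        raise FieldOfViewError("motion exceeds field of view")


def generate_patient(config: PhantomConfig, patient_id: Optional[str] = None) -> PatientSeries:
    """Generate all repeat series of one synthetic patient.

    Series 0 is the reference (pre-treatment) acquisition.  For every
    series ``k >= 1`` the bony anatomy, body outline and tissue texture are
    unchanged while the prostate is rigidly displaced by a fresh draw from
    the configured motion distribution; ``true_prostate_transforms[k]`` is
    exactly the applied motion and ``prostate_masks[k]`` is the reference
    delineation transported by it.  Output is deterministic for a fixed
    ``(config, seed)``.

    Raises
    ------
    FieldOfViewError
        If a drawn displacement pushes the prostate against the grid edge.
    """
    if patient_id is None:
        patient_id = f"phantom-{config.seed}"
    anat = _Anatomy(config, np.random.default_rng([config.seed, 0]))

    origin = config.origin_mm
    spacing = np.asarray(config.spacing_mm)
    xs = origin[0] + spacing[0] * np.arange(config.grid_shape[0])
    ys = origin[1] + spacing[1] * np.arange(config.grid_shape[1])
    zs = origin[2] + spacing[2] * np.arange(config.grid_shape[2])
    X = xs[:, None, None]
    Y = ys[None, :, None]
    Z = zs[None, None, :]
    edge = float(np.mean(spacing))

    static = _static_background(config, anat, X, Y, Z, edge)

    volumes, masks, transforms = [], [], []
    for k in range(config.n_series):
        if k == 0:
            transform = RigidTransform.identity(anat.prostate_center)
        else:
            motion_rng = np.random.default_rng([config.seed, k, 1])
            transform = _draw_motion(config, motion_rng, anat.prostate_center)
            _check_fov(config, anat, transform)

        vol = static.copy()

        # rectum / bladder: static position, series-varying size and content
        organ_rng = np.random.default_rng([config.seed, k, 2])
        s = config.organ_variation_scale
        r_rect = anat.rectum_radius * (1.0 + 0.15 * s * organ_rng.uniform(-1, 1))
        i_rect = 42.0 + 18.0 * s * organ_rng.uniform(-1, 1)
        r_blad = anat.bladder_radius * (1.0 + 0.10 * s * organ_rng.uniform(-1, 1))
        i_blad = _I_BLADDER - 8.0 * s * organ_rng.uniform(0, 1)
        blad = _ellipsoid_alpha(
            X, Y, Z, anat.bladder_center, (r_blad, r_blad, 1.15 * r_blad), edge
        )
        _paint(vol, blad, i_blad)
        rect = _tube_alpha(X, Y, anat.rectum_center_xy, r_rect, edge)
        _paint(vol, rect, i_rect)

        # moving prostate: evaluate reference-frame fields at pulled-back points
        if k == 0:
            P = (X, Y, Z)
        else:
            inv = transform.inverse()
            R = inv.rotation_matrix
            c = inv.center_mm
            t = inv.translation_mm
            # q = R (p - c) + c + t, broadcast without materializing (N,3)
            P = tuple(
                R[i, 0] * (X - c[0])
                + R[i, 1] * (Y - c[1])
                + R[i, 2] * (Z - c[2])
                + c[i]
                + t[i]
                for i in range(3)
            )
        alpha_p, int_p = _prostate_fields(anat, P, edge)
        _paint(vol, alpha_p, int_p)

        volume = ImageVolume(vol, spacing, origin)
        if config.noise_sigma > 0:
            volume = apply_noise(volume, config.noise_sigma, _seed_int(config.seed, k, 3))
        volumes.append(volume)
        masks.append(BinaryMask(alpha_p >= 0.5, spacing, origin))
        transforms.append(transform)

    return PatientSeries(volumes, masks, transforms, patient_id)
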