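"""Shared fixtures: phantoms at desk scale and the default seeded study."""

import numpy as np
import pytest
from scipy.ndimage import map_coordinates

import subvolreg as sv

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


#: tiny grid for structural tests (same field of view, very coarse)
TINY = dict(grid_shape=(48, 48, 30), spacing_mm=(449.28 / 48, 407.16 / 48, 204.0 / 30))


@pytest.fixture(scope="session")
def patient_series():
    """One default-grid patient with motion, organ variation and noise."""
    return sv.generate_patient(sv.PhantomConfig(seed=3))


@pytest.fixture(scope="session")
def quiet_series():
    """Noise-free, frozen-organ patient: only rigid prostate motion."""
    cfg = sv.PhantomConfig(seed=5, organ_variation_scale=0.0, noise_sigma=0.0)
    return sv.generate_patient(cfg)


@pytest.fixture(scope="session")
def default_study_report():
    """The full default synthetic study: 10 patients x 3 pairs x 5 volumes."""
    return sv.run_study(sv.StudyConfig(seed=7))


def warp_volume(
    volume: sv.ImageVolume, transform: sv.RigidTransform, order: int = 3
) -> sv.ImageVolume:
    """Resample so that ``out(p) = volume(T^{-1}(p))``: applies T to the content.

    Cubic splines by default: linear resampling blurs the fabricated fixed
    image asymmetrically relative to the sharp moving image, which biases
    recovery tests by a sizeable fraction of a voxel.
    """
    shape = volume.shape
    idx = np.indices(shape).reshape(3, -1).T
    pts = volume.origin_mm + idx * volume.spacing_mm
    src = transform.inverse().apply(pts)
    coords = (src - volume.origin_mm) / volume.spacing_mm
    data = map_coordinates(volume.data, coords.T, order=order, mode="nearest")
    return sv.ImageVolume(data.reshape(shape), volume.spacing_mm, volume.origin_mm)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
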