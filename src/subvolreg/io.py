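"""NIfTI and JSON persistence.

Volumes and masks are exchanged as NIfTI-1 (optionally gzipped).  On load,
images are reoriented to the canonical RAS layout and their affine must be
axis-aligned (orthogonal, diagonal up to tolerance); array axes then map
to the package's (RL, AP, CC) world frame.  Rigid transforms travel as
JSON objects ``{"versor": [x, y, z, w], "translation_mm": [...],
"center_mm": [...]}``, the same dialect for ground-truth phantom motion
and registration results.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np

from .errors import GeometryError
from .geometry import ImageVolume, RigidTransform
from .masks import BinaryMask


def _affine(spacing_mm, origin_mm) -> np.ndarray:
    A = np.eye(4)
    A[:3, :3] = np.diag(spacing_mm)
    A[:3, 3] = origin_mm
    return A


def save_volume(volume: ImageVolume, path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float32), _affine(volume.spacing_mm, volume.origin_mm))
    nib.save(img, str(path))


def save_mask(mask: BinaryMask, path) -> None:
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), _affine(mask.spacing_mm, mask.origin_mm))
    nib.save(img, str(path))


def _load_canonical(path):
    img = nib.as_closest_canonical(nib.load(str(path)))
    A = np.asarray(img.affine)
    off_diag = A[:3, :3] - np.diag(np.diag(A[:3, :3]))
    if np.abs(off_diag).max() > 1e-3:
        raise GeometryError(f"{path}: oblique affines are not supported")
    spacing = np.diag(A[:3, :3]).copy()
    if np.any(spacing <= 0):
        raise GeometryError(f"{path}: non-positive voxel spacing after reorientation")
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise GeometryError(f"{path}: expected a 3D image, got ndim={data.ndim}")
    return data, spacing, A[:3, 3].copy()


def load_volume(path) -> ImageVolume:
    data, spacing, origin = _load_canonical(path)
    return ImageVolume(np.asarray(data, dtype=float), spacing, origin)


def load_mask(path) -> BinaryMask:
    data, spacing, origin = _load_canonical(path)
    return BinaryMask(np.asarray(data) > 0.5, spacing, origin)


def save_transform(transform: RigidTransform, path, extra: Optional[dict] = None) -> None:
    d = transform.to_dict()
    if extra:
        d.update(extra)
    Path(path).write_text(json.dumps(d, indent=2))


def load_transform(path) -> RigidTransform:
    return RigidTransform.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------- #
# patient series directories
# ---------------------------------------------------------------------- #

_VOL_FMT = "series_{:02d}.nii.gz"
_MASK_FMT = "prostate_{:02d}.nii.gz"
_TF_FMT = "true_transform_{:02d}.json"


def save_patient_series(series, out_dir, write_transforms: bool = True) -> Path:
    """Write one patient's volumes, prostate masks and ground-truth transforms."""
    out = Path(out_dir) / series.patient_id
    out.mkdir(parents=True, exist_ok=True)
    for k, (vol, mask) in enumerate(zip(series.volumes, series.prostate_masks)):
        save_volume(vol, out / _VOL_FMT.format(k))
        save_mask(mask, out / _MASK_FMT.format(k))
        if write_transforms and series.true_prostate_transforms:
            save_transform(series.true_prostate_transforms[k], out / _TF_FMT.format(k))
    return out
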