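"""Alignment to the forearm long axis and standardized VOI extraction.

Convention: the third array axis is the long axis of the forearm and +z points
distally.  The analysed VOI is a 10 mm stack of slices that starts 9.5 mm
proximal to a reference line placed at the endplate of the distal radius (the
usual distal-radius HR-pQCT protocol); the reference slice itself is supplied
by the user (or by synthetic ground truth) — endplate localisation is a manual
step and is not automated here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import Volume


@dataclass
class VOISpec:
    offset_mm: float = 9.5
    length_mm: float = 10.0
    reference_slice: int | None = None

    def __post_init__(self) -> None:
        if self.offset_mm < 0 or self.length_mm <= 0:
            raise ValueError("offset must be >= 0 and length > 0")


def _round_half_away(x: float) -> int:
    return int(np.floor(abs(x) + 0.5) * np.sign(x)) if x else 0


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping the unit vector ``axis`` onto +z (Rodrigues)."""
    z = np.array([0.0, 0.0, 1.0])
    axis = axis / np.linalg.norm(axis)
    if axis[2] < 0:
        axis = -axis
    v = np.cross(axis, z)
    c = float(axis @ z)
    s = np.linalg.norm(v)
    if s < 1e-12:
        return np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def principal_axis(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Dominant axis of the mask's second-moment (inertia-like) tensor.

    Returns (unit axis, eigenvalues sorted descending).
    """
    pts = np.argwhere(mask)
    if pts.size == 0:
        raise ValueError("empty mask has no principal axis")
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return evecs[:, order[0]], evals[order]


def align_to_long_axis(volume: Volume, coarse_bone_mask: np.ndarray,
                       order: int = 1) -> tuple[Volume, np.ndarray]:
    """Rotate so the bone's principal axis coincides with the z axis.

    Trilinear resampling for grey/HU/density volumes (``order=1``); pass
    ``order=0`` for label images.  Returns the rotated volume and the applied
    rotation matrix (identity, with a warning, if the mask has no dominant
    axis).
    """
    axis, evals = principal_axis(coarse_bone_mask)
    if evals[0] < 1.05 * evals[1]:
        warnings.warn("mask has no dominant axis; returning identity rotation",
                      stacklevel=2)
        return volume.with_data(volume.data.copy()), np.eye(3)
    rot = _rotation_to_z(axis)
    centre = (np.array(volume.shape) - 1) / 2.0
    # affine_transform maps output coords -> input coords, so use the inverse
    inv = rot.T
    offset = centre - inv @ centre
    rotated = ndimage.affine_transform(
        np.asarray(volume.data, float), inv, offset=offset, order=order,
        mode="constant", cval=float(np.min(volume.data)))
    out = volume.with_data(rotated, rotation=rot.tolist())
    return out, rot


def extract_voi(volume: Volume, spec: VOISpec,
                voxel_size_mm: float | None = None) -> Volume:
    """Cut the standardized VOI proximal to the reference slice.

    The VOI covers ``round(length/voxel)`` slices whose *distal-most* slice
    sits ``round(offset/voxel)`` slices proximal to the reference slice
    (rounding half away from zero).  With 0.125 mm voxels and the defaults
    that is 80 slices starting 76 slices from the reference.
    """
    if spec.reference_slice is None:
        raise ValueError("reference_slice must be provided (manual endplate "
                         "localisation)")
    h = voxel_size_mm or volume.voxel_size_mm
    off = _round_half_away(spec.offset_mm / h)
    length = _round_half_away(spec.length_mm / h)
    hi = spec.reference_slice - off          # distal-most VOI slice (inclusive)
    lo = hi - length + 1
    nz = volume.shape[2]
    if lo < 0 or hi >= nz:
        missing = [s for s in range(lo, hi + 1) if s < 0 or s >= nz]
        raise ValueError(
            f"VOI slices {lo}..{hi} exceed volume extent 0..{nz - 1}; "
            f"missing slices {missing[:5]}{'...' if len(missing) > 5 else ''}")
    sub = volume.data[:, :, lo:hi + 1]
    return volume.with_data(sub, voi={"lo": lo, "hi": hi,
                                      "offset_slices": off,
                                      "length_slices": length})
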