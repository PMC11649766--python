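"""Lightweight 3D volume container with NIfTI round-trip.

A volume is a dense ``(nx, ny, nz)`` array on an isotropic grid plus the voxel
edge length in mm and a free-form metadata dict.  The third axis is the long
(proximal->distal) axis of the forearm; +z points distally.  The same container
carries a volume through its three calibration states (vendor grey values,
Hounsfield units, HA-equivalent mass density) — the ``kind`` field records
which state it is in, and conversion functions update it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

#: allowed calibration states
KINDS = ("grey", "hu", "density", "mask", "labels")


@dataclass
class Volume:
    data: np.ndarray
    voxel_size_mm: float
    kind: str = "grey"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.kind not in KINDS:
            raise ValueError(f"unknown volume kind {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.voxel_size_mm) ** 3

    def with_data(self, data: np.ndarray, kind: str | None = None, **meta) -> "Volume":
        """Copy of this volume with new voxel data (and optionally a new kind)."""
        out = replace(self, data=data, kind=kind or self.kind)
        out.meta = {**self.meta, **meta}
        return out

    # --- IO -----------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write as NIfTI; the affine encodes the isotropic voxel size."""
        affine = np.diag([self.voxel_size_mm] * 3 + [1.0])
        data = self.data
        if self.kind in ("mask", "labels"):
            data = data.astype(np.uint8)
        nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))

    @classmethod
    def load(cls, path: str | Path, kind: str = "grey") -> "Volume":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        if not np.allclose(zooms, zooms[0], rtol=1e-4):
            raise ValueError(f"anisotropic voxels {zooms} are not supported")
        data = np.asarray(img.dataobj)
        if kind in ("mask", "labels"):
            data = data.astype(np.uint8)
        else:
            data = data.astype(np.float64)
        return cls(data=data, voxel_size_mm=float(zooms[0]), kind=kind)
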