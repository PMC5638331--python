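"""In-memory 3D label and probability images with physical voxel dimensions.

Thin containers around numpy arrays plus NIfTI-1 read/write through nibabel.
Orientation metadata (the affine) is carried opaquely and never interpreted;
all operations in this package work on the voxel grid and voxel dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["LabelImage", "ProbabilityImage", "load_label_image", "load_probability_image"]


def _default_affine(voxel_dims: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_dims
    return aff


def _as_voxel_dims(voxel_dims) -> np.ndarray:
    vd = np.asarray(voxel_dims, dtype=float)
    if vd.shape != (3,):
        raise ValueError(f"voxel_dims must be a 3-vector, got shape {vd.shape}")
    if np.any(vd <= 0):
        raise ValueError(f"voxel_dims must be strictly positive, got {vd}")
    return vd


@dataclass
class LabelImage:
    """3D integer label grid with voxel dimensions in mm."""

    data: np.ndarray
    voxel_dims: np.ndarray
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label grid must be 3D, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.array_equal(rounded, self.data):
                raise ValueError("label grid must hold integers")
            self.data = rounded.astype(np.int32)
        if self.data.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        self.voxel_dims = _as_voxel_dims(self.voxel_dims)
        if self.affine is None:
            self.affine = _default_affine(self.voxel_dims)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_dims))

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.int16), self.affine)
        img.header.set_zooms(tuple(self.voxel_dims))
        nib.save(img, str(path))


@dataclass
class ProbabilityImage:
    """3D real-valued grid of per-voxel label probabilities in [0, 1]."""

    data: np.ndarray
    voxel_dims: np.ndarray
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"probability grid must be 3D, got ndim={self.data.ndim}")
        if self.data.min(initial=0.0) < 0.0 or self.data.max(initial=0.0) > 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
        self.voxel_dims = _as_voxel_dims(self.voxel_dims)
        if self.affine is None:
            self.affine = _default_affine(self.voxel_dims)

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms(tuple(self.voxel_dims))
        nib.save(img, str(path))


def load_label_image(path: str | Path) -> LabelImage:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return LabelImage(
        data=np.rint(data).astype(np.int32),
        voxel_dims=np.asarray(img.header.get_zooms()[:3], dtype=float),
        affine=np.asarray(img.affine),
    )


def load_probability_image(path: str | Path) -> ProbabilityImage:
    img = nib.load(str(path))
    return ProbabilityImage(
        data=np.asarray(img.dataobj, dtype=float),
        voxel_dims=np.asarray(img.header.get_zooms()[:3], dtype=float),
        affine=np.asarray(img.affine),
    )
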