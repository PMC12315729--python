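"""NIfTI and plain-text I/O for the core volumetric types.

Conventions (see README):
- ScalarImage: 3-D NIfTI; the NIfTI affine is the voxel-to-world mapping.
- DisplacementField: 4-D NIfTI with 3 components on the last axis, world-mm
  displacements on the field's own grid.
- TensorImage: 4-D NIfTI with 6 components ordered Dxx, Dxy, Dxz, Dyy, Dyz,
  Dzz (lower-triangle row order); the valid mask is recomputed on load.
- AffineTransform: 4x4 whitespace-separated plain-text matrix, world-mm to
  world-mm (FLIRT-like dialect without the voxel scaling).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .types import (
    AffineTransform,
    DisplacementField,
    ImageGrid,
    ScalarImage,
    TensorImage,
)

__all__ = [
    "load_scalar",
    "save_scalar",
    "load_displacement",
    "save_displacement",
    "load_tensor",
    "save_tensor",
    "load_affine",
    "save_affine",
]


def _grid_from_nifti(img) -> ImageGrid:
    return ImageGrid(tuple(int(s) for s in img.shape[:3]), np.asarray(img.affine))


def load_scalar(path: str | Path) -> ScalarImage:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3-D volume, got shape {data.shape}")
    return ScalarImage(_grid_from_nifti(img), data)


def save_scalar(image: ScalarImage, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(image.values.astype(np.float32),
                             image.grid.voxel_to_world), str(path))


def load_displacement(path: str | Path) -> DisplacementField:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    data = np.squeeze(data)  # tolerate the 5-dim (x,y,z,1,3) convention
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"{path}: expected (x,y,z,3) displacement, got {data.shape}")
    return DisplacementField(_grid_from_nifti(img), data)


def save_displacement(field: DisplacementField, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(field.disp.astype(np.float32),
                             field.grid.voxel_to_world), str(path))


def load_tensor(path: str | Path) -> TensorImage:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    data = np.squeeze(data)
    if data.ndim != 4 or data.shape[-1] != 6:
        raise ValueError(f"{path}: expected (x,y,z,6) tensor volume, got {data.shape}")
    return TensorImage(_grid_from_nifti(img), data)


def save_tensor(timg: TensorImage, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(timg.components.astype(np.float32),
                             timg.grid.voxel_to_world), str(path))


def load_affine(path: str | Path, dof_tag: str = "affine12") -> AffineTransform:
    mat = np.loadtxt(str(path))
    if mat.shape != (4, 4):
        raise ValueError(f"{path}: expected a 4x4 matrix, got shape {mat.shape}")
    return AffineTransform(mat, dof_tag)


def save_affine(affine: AffineTransform, path: str | Path) -> None:
    np.savetxt(str(path), affine.matrix, fmt="%.10g")
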