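"""Tensor-field operations: log-Euclidean averaging, FA, PPD reorientation."""

from __future__ import annotations

import numpy as np

from .types import (
    GridMismatchError,
    ScalarImage,
    TensorImage,
    matrices_to_components,
)

__all__ = [
    "tensor_log",
    "tensor_exp",
    "log_euclidean_mean",
    "log_euclidean_mean_images",
    "fa_from_eigenvalues",
    "fa_map",
    "ppd_rotation",
    "voxelwise_median",
    "voxelwise_mean_valid",
]

#: eigenvalues are clamped below at this fraction of the largest eigenvalue
#: before taking matrix logs; a voxel whose largest eigenvalue is <= 0 is invalid
EIGENVALUE_CLAMP_FRACTION = 1e-9


def tensor_log(mats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Matrix log of (...,3,3) symmetric tensors with eigenvalue clamping.

    Returns (log_mats, ok) where ok is False where the largest eigenvalue
    is non-positive (log undefined even after clamping).
    """
    evals, evecs = np.linalg.eigh(np.asarray(mats, dtype=float))
    lmax = evals[..., -1]
    ok = lmax > 0
    floor = np.where(ok, EIGENVALUE_CLAMP_FRACTION * lmax, 1.0)
    clamped = np.maximum(evals, floor[..., None])
    logl = np.log(np.where(ok[..., None], clamped, 1.0))
    out = np.einsum("...ik,...k,...jk->...ij", evecs, logl, evecs)
    return out, ok


def tensor_exp(mats: np.ndarray) -> np.ndarray:
    """Matrix exp of (...,3,3) symmetric matrices."""
    evals, evecs = np.linalg.eigh(np.asarray(mats, dtype=float))
    return np.einsum("...ik,...k,...jk->...ij", evecs, np.exp(evals), evecs)


def log_euclidean_mean(tensors: np.ndarray, valid: np.ndarray | None = None):
    """Log-Euclidean mean over the first axis of (N, ..., 3, 3) tensors.

    Only valid tensors contribute at each position.  Returns
    (mean: (...,3,3), any_valid: (...,) bool); positions with no valid
    contributor get a zero tensor.
    """
    tensors = np.asarray(tensors, dtype=float)
    logs, ok = tensor_log(tensors)
    if valid is not None:
        ok = ok & np.asarray(valid, dtype=bool)
    count = ok.sum(axis=0)
    any_valid = count > 0
    w = ok.astype(float)[..., None, None]
    mean_log = (logs * w).sum(axis=0) / np.maximum(count, 1)[..., None, None]
    mean = tensor_exp(mean_log)
    mean = np.where(any_valid[..., None, None], mean, 0.0)
    return mean, any_valid


def log_euclidean_mean_images(timgs: list[TensorImage]) -> TensorImage:
    """Voxel-wise log-Euclidean mean across subjects, valid voxels only."""
    if not timgs:
        raise ValueError("need at least one tensor image")
    grid = timgs[0].grid
    for t in timgs[1:]:
        if not grid.same_as(t.grid):
            raise GridMismatchError("tensor images must share one grid")
    mats = np.stack([t.as_matrices() for t in timgs])
    valid = np.stack([t.valid for t in timgs])
    mean, any_valid = log_euclidean_mean(mats, valid)
    return TensorImage(grid, matrices_to_components(mean), any_valid)


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from (..., 3) eigenvalues; 0 for zero tensors."""
    evals = np.asarray(evals, dtype=float)
    mean = evals.mean(axis=-1, keepdims=True)
    num = ((evals - mean) ** 2).sum(axis=-1)
    den = (evals ** 2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    return np.where(den > 0, np.clip(fa, 0.0, 1.0), 0.0)


def fa_map(timg: TensorImage) -> ScalarImage:
    """FA per voxel; 0 where the tensor is invalid."""
    evals = np.linalg.eigvalsh(timg.as_matrices())
    fa = fa_from_eigenvalues(evals)
    return ScalarImage(timg.grid, np.where(timg.valid, fa, 0.0))


def ppd_rotation(F: np.ndarray, mats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Preservation-of-principal-directions rotation for tensors under map F.

    ``F`` (..., 3, 3) is the local linear transformation acting on the anatomy;
    ``mats`` (..., 3, 3) the tensors.  The principal eigenvector e1 is mapped
    to F e1 (normalised); the secondary direction follows F e2 projected
    orthogonally to the new e1.  Returns (R, ok); ok is False where F is
    (numerically) singular, in which case R is identity.
    """
    F = np.asarray(F, dtype=float)
    mats = np.asarray(mats, dtype=float)
    ok = np.abs(np.linalg.det(F)) > 1e-12
    evals, evecs = np.linalg.eigh(mats)
    e1 = evecs[..., :, 2]  # eigenvectors sorted ascending
    e2 = evecs[..., :, 1]
    n1 = np.einsum("...ij,...j->...i", F, e1)
    n1_norm = np.linalg.norm(n1, axis=-1, keepdims=True)
    n1 = n1 / np.where(n1_norm > 0, n1_norm, 1.0)
    v2 = np.einsum("...ij,...j->...i", F, e2)
    v2 = v2 - np.einsum("...i,...i->...", v2, n1)[..., None] * n1
    v2_norm = np.linalg.norm(v2, axis=-1, keepdims=True)
    n2 = v2 / np.where(v2_norm > 0, v2_norm, 1.0)
    n3 = np.cross(n1, n2)
    # R maps the old eigenframe (e1,e2,e3) to the new frame (n1,n2,n3)
    e3 = evecs[..., :, 0]
    new = np.stack([n1, n2, n3], axis=-1)
    old = np.stack([e1, e2, e3], axis=-1)
    R = new @ np.swapaxes(old, -1, -2)
    degen = (n1_norm[..., 0] <= 1e-12) | (v2_norm[..., 0] <= 1e-12)
    ok = ok & ~degen
    eye = np.broadcast_to(np.eye(3), R.shape)
    R = np.where(ok[..., None, None], R, eye)
    return R, ok


def voxelwise_median(images: list[ScalarImage]) -> ScalarImage:
    if not images:
        raise ValueError("need at least one image")
    grid = images[0].grid
    for im in images[1:]:
        if not grid.same_as(im.grid):
            raise GridMismatchError("images must share one grid")
    return ScalarImage(grid, np.median([im.values for im in images], axis=0))


def voxelwise_mean_valid(images: list[ScalarImage],
                         valid_masks: list[np.ndarray]) -> ScalarImage:
    """Mean over subjects using only voxels flagged valid; 0 where none valid."""
    if not images:
        raise ValueError("need at least one image")
    if len(images) != len(valid_masks):
        raise ValueError("one valid mask per image required")
    grid = images[0].grid
    for im in images[1:]:
        if not grid.same_as(im.grid):
            raise GridMismatchError("images must share one grid")
    vals = np.stack([im.values for im in images])
    valid = np.stack([np.asarray(m, dtype=bool) for m in valid_masks])
    count = valid.sum(axis=0)
    total = (vals * valid).sum(axis=0)
    return ScalarImage(grid, np.where(count > 0, total / np.maximum(count, 1), 0.0))
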