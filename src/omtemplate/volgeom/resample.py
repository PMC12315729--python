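"""Resampling of scalar and tensor images through warps and affines."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .tensor import ppd_rotation, tensor_exp, tensor_log
from .types import (
    AffineTransform,
    DisplacementField,
    ImageGrid,
    ScalarImage,
    TensorImage,
    components_to_matrices,
    matrices_to_components,
)
from .warp import jacobian_matrices

__all__ = ["resample_scalar", "resample_tensor"]

Mapping = DisplacementField | AffineTransform


def _target_positions(mapping: Mapping, out_grid: ImageGrid | None):
    """Resolve the output grid and the world points to sample the source at."""
    if isinstance(mapping, DisplacementField):
        grid = mapping.grid if out_grid is None else out_grid
        if out_grid is not None and not grid.same_as(mapping.grid):
            raise ValueError("out_grid must match the displacement field's grid")
        return grid, mapping.positions()
    if isinstance(mapping, AffineTransform):
        if out_grid is None:
            raise ValueError("out_grid is required when mapping is an affine")
        return out_grid, mapping.apply(out_grid.world_coords())
    raise TypeError(f"unsupported mapping type {type(mapping)!r}")


def resample_scalar(image: ScalarImage, mapping: Mapping, order: int = 3,
                    out_grid: ImageGrid | None = None) -> ScalarImage:
    """Pull ``image`` back through ``mapping`` onto the output grid.

    The output value at grid point x is the source interpolated at the mapped
    point; points outside the source field of view get 0.  Spline order 3 is
    the default for intensities; use order 1 (trilinear) for masks.
    """
    if not isinstance(order, (int, np.integer)) or not 0 <= order <= 5:
        raise ValueError(f"interpolation order must be an int in [0, 5], got {order}")
    grid, pts = _target_positions(mapping, out_grid)
    vox = image.grid.world_to_voxel_coords(pts).reshape(3, -1)
    vals = ndimage.map_coordinates(image.values, vox, order=order,
                                   mode="constant", cval=0.0)
    return ScalarImage(grid, vals.reshape(grid.shape))


def resample_tensor(timg: TensorImage, mapping: Mapping,
                    out_grid: ImageGrid | None = None) -> TensorImage:
    """Pull a tensor image back through ``mapping`` with PPD reorientation.

    Components are interpolated trilinearly in log-tensor space (this avoids
    swelling across interfaces); each interpolated tensor is then reoriented
    by the preservation-of-principal-directions rule using the local Jacobian
    of the map.  Since the mapping is a pullback (output space -> source
    space), the anatomy transformation is its inverse: F = J^-1.

    The output valid mask is False wherever any contributing source voxel is
    invalid, the mapped point falls outside the source grid, or the local
    Jacobian is singular.
    """
    grid, pts = _target_positions(mapping, out_grid)
    vox = timg.grid.world_to_voxel_coords(pts).reshape(3, -1)

    # log-transform valid source tensors; invalid voxels must not contribute
    log_mats, _ = tensor_log(timg.as_matrices())
    log_mats[~timg.valid] = 0.0
    log_comp = matrices_to_components(log_mats)

    interp = np.empty((int(np.prod(grid.shape)), 6))
    for c in range(6):
        interp[:, c] = ndimage.map_coordinates(log_comp[..., c], vox, order=1,
                                               mode="constant", cval=0.0)
    # a target voxel is valid only if every contributing source voxel is valid
    # and the point is inside the source FOV: interpolate the indicator
    indicator = ndimage.map_coordinates(timg.valid.astype(float), vox, order=1,
                                        mode="constant", cval=0.0)
    valid = (indicator > 1.0 - 1e-6).reshape(grid.shape)

    mats = tensor_exp(components_to_matrices(interp))

    # local Jacobian of the map at each output voxel
    if isinstance(mapping, AffineTransform):
        J = np.broadcast_to(mapping.linear, (mats.shape[0], 3, 3))
    else:
        J = jacobian_matrices(mapping).reshape(-1, 3, 3)
    det = np.linalg.det(J)
    ok_J = np.abs(det) > 1e-12
    F = np.empty_like(np.broadcast_to(np.eye(3), J.shape).copy())
    F[ok_J] = np.linalg.inv(J[ok_J])
    F[~ok_J] = np.eye(3)

    R, ok_R = ppd_rotation(F, mats)
    mats = np.einsum("...ij,...jk,...lk->...il", R, mats, R)
    valid = valid & (ok_J & ok_R).reshape(grid.shape)

    comp = matrices_to_components(mats).reshape(grid.shape + (6,))
    comp[~valid] = 0.0
    return TensorImage(grid, comp, valid)
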