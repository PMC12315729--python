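"""Displacement-field algebra: composition, inversion, averaging, Jacobians."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .types import (
    AffineTransform,
    DisplacementField,
    GridMismatchError,
    ImageGrid,
    ScalarImage,
)

__all__ = [
    "compose_warps",
    "compose_affine_warp",
    "invert_warp",
    "mean_warp",
    "jacobian_determinant_map",
    "jacobian_matrices",
    "sample_displacement",
    "WarpInversionError",
]


class WarpInversionError(RuntimeError):
    pass


def sample_displacement(field: DisplacementField, world_points: np.ndarray,
                        return_oob_count: bool = False):
    """Interpolate a displacement field (trilinear) at arbitrary world points.

    Points outside the field's grid are evaluated with boundary-clamped
    (nearest-edge) interpolation.
    """
    vox = field.grid.world_to_voxel_coords(world_points)
    flat = vox.reshape(3, -1)
    oob = int(np.count_nonzero(
        np.any((flat < 0) | (flat > (np.array(field.grid.shape)[:, None] - 1)), axis=0)
    ))
    out = np.empty((3,) + flat.shape[1:])
    for c in range(3):
        out[c] = ndimage.map_coordinates(
            field.disp[..., c], flat, order=1, mode="nearest"
        )
    out = out.reshape(world_points.shape)
    if return_oob_count:
        return out, oob
    return out


def compose_warps(outer: DisplacementField, inner: DisplacementField,
                  return_oob_count: bool = False):
    """Compose two warps: result(x) = outer(inner(x)).

    ``inner``'s grid is the grid of the result; ``outer``'s displacement is
    interpolated at the points ``inner`` maps to (boundary-clamped, with an
    out-of-bounds count available).
    """
    pts = inner.positions()
    d_outer, oob = sample_displacement(outer, pts, return_oob_count=True)
    disp = inner.disp + np.moveaxis(d_outer, 0, -1)
    result = DisplacementField(inner.grid, disp)
    if return_oob_count:
        return result, oob
    return result


def compose_affine_warp(affine: AffineTransform, warp: DisplacementField) -> DisplacementField:
    """result(x) = affine(warp(x)), exact (no interpolation of the affine part)."""
    pts = warp.positions()
    mapped = affine.apply(pts)
    x = warp.grid.world_coords()
    return DisplacementField(warp.grid, np.moveaxis(mapped - x, 0, -1))


def invert_warp(warp: DisplacementField, tol: float = 0.01, max_iter: int = 50,
                check: bool = True) -> DisplacementField:
    """Fixed-point inversion: d_inv(x) <- -d(x + d_inv(x)), starting at -d.

    Convergence requires the displacement to be smooth relative to the grid
    spacing (a contraction).  With ``check`` the composition residual
    ``|w(w_inv(x)) - x|`` must fall below ``tol`` (mm) on >= 99% of grid
    points, otherwise :class:`WarpInversionError` is raised.
    """
    x = warp.grid.world_coords()
    d_inv = -warp.disp.copy()
    for _ in range(max_iter):
        pts = x + np.moveaxis(d_inv, -1, 0)
        d_at = sample_displacement(warp, pts)
        new = -np.moveaxis(d_at, 0, -1)
        delta = np.max(np.abs(new - d_inv))
        d_inv = new
        if delta < 0.1 * tol:
            break
    inv = DisplacementField(warp.grid, d_inv)
    if check:
        resid = np.linalg.norm(
            np.moveaxis(sample_displacement(warp, inv.positions()), 0, -1) + inv.disp,
            axis=-1,
        )
        frac_bad = float(np.mean(resid > tol))
        if frac_bad > 0.01:
            raise WarpInversionError(
                f"inversion residual > {tol} mm on {100 * frac_bad:.1f}% of voxels "
                f"(max residual {resid.max():.3g} mm)"
            )
    return inv


def mean_warp(warps: list[DisplacementField]) -> DisplacementField:
    """Voxel-wise Euclidean (small-deformation) mean of displacement vectors."""
    if not warps:
        raise ValueError("mean_warp requires at least one field")
    grid = warps[0].grid
    for w in warps[1:]:
        if not grid.same_as(w.grid):
            raise GridMismatchError("all fields must share one grid")
    disp = np.mean([w.disp for w in warps], axis=0)
    return DisplacementField(grid, disp)


def _spatial_gradients(disp: np.ndarray, grid: ImageGrid) -> np.ndarray:
    """d(d_c)/d(world_j) as (*shape, 3, 3): rows=component, cols=world axis.

    Central differences in the interior, one-sided at the boundary, converted
    from voxel-index derivatives to world derivatives via the grid affine.
    """
    shape = grid.shape
    g_vox = np.empty(shape + (3, 3))
    for c in range(3):
        grads = np.gradient(disp[..., c], edge_order=1)
        for j in range(3):
            g_vox[..., c, j] = grads[j]
    # chain rule: d/dworld = d/dvox @ dvox/dworld
    vox_from_world = grid.world_to_voxel[:3, :3]
    return g_vox @ vox_from_world


def jacobian_matrices(warp: DisplacementField) -> np.ndarray:
    """(*shape, 3, 3) Jacobian of phi(x) = x + d(x) in world units."""
    if any(s < 2 for s in warp.grid.shape):
        raise ValueError("need >= 2 voxels per axis for derivatives")
    J = _spatial_gradients(warp.disp, warp.grid)
    J[..., 0, 0] += 1.0
    J[..., 1, 1] += 1.0
    J[..., 2, 2] += 1.0
    return J


def jacobian_determinant_map(warp: DisplacementField) -> ScalarImage:
    """Voxel-wise det of the spatial Jacobian of phi(x) = x + d(x)."""
    return ScalarImage(warp.grid, np.linalg.det(jacobian_matrices(warp)))
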