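"""Core volumetric types: grids, images, tensors, affines and displacement fields.

All geometry flows through a single 4x4 voxel-to-world affine per grid
(0-based voxel indices, world coordinates in mm).  Displacement fields store
world-mm offsets on the grid of the space they are *defined on*: a field ``w``
represents the map ``phi(x) = x + w(x)`` and is used as a pullback resampling
map from that space into the space ``phi`` points at.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ImageGrid",
    "ScalarImage",
    "TensorImage",
    "AffineTransform",
    "DisplacementField",
    "WeightImage",
    "GridMismatchError",
]

# lower-triangle row order of the 6 unique components of a symmetric 3x3 matrix
TENSOR_COMPONENT_ORDER = ("Dxx", "Dxy", "Dxz", "Dyy", "Dyz", "Dzz")
_TRI_I = np.array([0, 0, 0, 1, 1, 2])
_TRI_J = np.array([0, 1, 2, 1, 2, 2])


class GridMismatchError(ValueError):
    """Raised when an operation receives images on incompatible grids."""


@dataclass(frozen=True)
class ImageGrid:
    """A regular 3-D sampling grid with its voxel-to-world mapping."""

    shape: tuple[int, int, int]
    voxel_to_world: np.ndarray  # 4x4, mm

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be 3 positive ints, got {self.shape}")
        vtw = np.asarray(self.voxel_to_world, dtype=float)
        if vtw.shape != (4, 4):
            raise ValueError("voxel_to_world must be 4x4")
        if abs(np.linalg.det(vtw)) < 1e-12:
            raise ValueError("voxel_to_world must be invertible")
        sizes = np.linalg.norm(vtw[:3, :3], axis=0)
        if np.any(sizes <= 0):
            raise ValueError("voxel sizes must be strictly positive")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_to_world", vtw)

    @property
    def world_to_voxel(self) -> np.ndarray:
        return np.linalg.inv(self.voxel_to_world)

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.linalg.norm(self.voxel_to_world[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.voxel_to_world[:3, :3])))

    def voxel_coords(self) -> np.ndarray:
        """(3, *shape) array of voxel indices."""
        return np.asarray(
            np.meshgrid(*(np.arange(s) for s in self.shape), indexing="ij"),
            dtype=float,
        )

    def world_coords(self) -> np.ndarray:
        """(3, *shape) array of world coordinates of all voxel centers."""
        ijk = self.voxel_coords().reshape(3, -1)
        xyz = self.voxel_to_world[:3, :3] @ ijk + self.voxel_to_world[:3, 3:4]
        return xyz.reshape((3,) + self.shape)

    def world_to_voxel_coords(self, points: np.ndarray) -> np.ndarray:
        """Map (3, ...) world points to continuous voxel coordinates."""
        pts = np.asarray(points, dtype=float)
        flat = pts.reshape(3, -1)
        wtv = self.world_to_voxel
        ijk = wtv[:3, :3] @ flat + wtv[:3, 3:4]
        return ijk.reshape(pts.shape)

    def same_as(self, other: "ImageGrid", tol: float = 1e-6) -> bool:
        return self.shape == other.shape and bool(
            np.allclose(self.voxel_to_world, other.voxel_to_world, atol=tol)
        )

    @staticmethod
    def isotropic(shape: tuple[int, int, int], voxel_size: float,
                  origin: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> "ImageGrid":
        vtw = np.eye(4)
        vtw[0, 0] = vtw[1, 1] = vtw[2, 2] = voxel_size
        vtw[:3, 3] = origin
        return ImageGrid(tuple(shape), vtw)


def _check_grid(grid: ImageGrid, array: np.ndarray, ncomp: int | None = None) -> np.ndarray:
    arr = np.asarray(array, dtype=float)
    expect = grid.shape if ncomp is None else grid.shape + (ncomp,)
    if arr.shape != expect:
        raise GridMismatchError(f"array shape {arr.shape} != expected {expect}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    return arr


@dataclass
class ScalarImage:
    grid: ImageGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_grid(self.grid, self.values)

    def copy(self) -> "ScalarImage":
        return ScalarImage(self.grid, self.values.copy())


@dataclass
class WeightImage:
    """Nonnegative per-voxel weights (e.g. soft masks)."""

    grid: ImageGrid
    weights: np.ndarray
    mean_normalised: bool = False

    def __post_init__(self) -> None:
        self.weights = _check_grid(self.grid, self.weights)
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if self.mean_normalised and abs(self.weights.mean() - 1.0) > 1e-6:
            raise ValueError("mean-normalised weights must have whole-volume mean 1")


@dataclass
class TensorImage:
    """Symmetric 3x3 tensor per voxel, stored as 6 components (Dxx Dxy Dxz Dyy Dyz Dzz).

    ``valid`` is False wherever the tensor is zero or not positive definite;
    averaging and FA treat invalid voxels as missing data.
    """

    grid: ImageGrid
    components: np.ndarray  # (*shape, 6)
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.components = _check_grid(self.grid, self.components, ncomp=6)
        if self.valid is None:
            self.valid = compute_tensor_validity(self.components)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.grid.shape:
                raise GridMismatchError("valid mask shape mismatch")

    def as_matrices(self) -> np.ndarray:
        """(*shape, 3, 3) dense symmetric matrices."""
        return components_to_matrices(self.components)

    @staticmethod
    def from_matrices(grid: ImageGrid, mats: np.ndarray,
                      valid: np.ndarray | None = None) -> "TensorImage":
        return TensorImage(grid, matrices_to_components(mats), valid)

    def copy(self) -> "TensorImage":
        return TensorImage(self.grid, self.components.copy(), self.valid.copy())


def components_to_matrices(comp: np.ndarray) -> np.ndarray:
    comp = np.asarray(comp, dtype=float)
    mats = np.zeros(comp.shape[:-1] + (3, 3))
    mats[..., _TRI_I, _TRI_J] = comp
    mats[..., _TRI_J, _TRI_I] = comp
    return mats


def matrices_to_components(mats: np.ndarray) -> np.ndarray:
    mats = np.asarray(mats, dtype=float)
    return mats[..., _TRI_I, _TRI_J]


def compute_tensor_validity(components: np.ndarray) -> np.ndarray:
    """Valid = nonzero and positive definite (all eigenvalues > 0)."""
    mats = components_to_matrices(components)
    nonzero = np.any(components != 0, axis=-1)
    valid = np.zeros(components.shape[:-1], dtype=bool)
    if np.any(nonzero):
        evals = np.linalg.eigvalsh(mats[nonzero])
        valid[nonzero] = np.all(evals > 0, axis=-1)
    return valid


@dataclass(frozen=True)
class AffineTransform:
    """World-to-world 4x4 affine (mm)."""

    matrix: np.ndarray
    dof_tag: str = "affine12"

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        if mat.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if abs(np.linalg.det(mat)) < 1e-12:
            raise ValueError("affine matrix must be invertible")
        if self.dof_tag not in ("rigid6", "affine12"):
            raise ValueError(f"unknown dof_tag {self.dof_tag!r}")
        if self.dof_tag == "rigid6":
            R = mat[:3, :3]
            if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
                raise ValueError("rigid6 requires a proper rotation in the 3x3 block")
        object.__setattr__(self, "matrix", mat)

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to (3, ...) world points."""
        pts = np.asarray(points, dtype=float)
        flat = pts.reshape(3, -1)
        out = self.linear @ flat + self.translation[:, None]
        return out.reshape(pts.shape)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix), self.dof_tag)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self after other: (self o other)(x) = self(other(x))."""
        tag = "rigid6" if self.dof_tag == other.dof_tag == "rigid6" else "affine12"
        return AffineTransform(self.matrix @ other.matrix, tag)

    @staticmethod
    def identity() -> "AffineTransform":
        return AffineTransform(np.eye(4), "rigid6")

    @staticmethod
    def translation_mm(t) -> "AffineTransform":
        mat = np.eye(4)
        mat[:3, 3] = t
        return AffineTransform(mat, "rigid6")


@dataclass
class DisplacementField:
    """Dense world-mm displacement on a reference grid; phi(x) = x + disp(x)."""

    grid: ImageGrid
    disp: np.ndarray  # (*shape, 3)

    def __post_init__(self) -> None:
        self.disp = _check_grid(self.grid, self.disp, ncomp=3)

    def positions(self) -> np.ndarray:
        """(3, *shape) world coordinates phi(x) for every grid point x."""
        return self.grid.world_coords() + np.moveaxis(self.disp, -1, 0)

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.disp, axis=-1)

    def copy(self) -> "DisplacementField":
        return DisplacementField(self.grid, self.disp.copy())

    @staticmethod
    def zero(grid: ImageGrid) -> "DisplacementField":
        return DisplacementField(grid, np.zeros(grid.shape + (3,)))

    @staticmethod
    def from_affine(affine: AffineTransform, grid: ImageGrid) -> "DisplacementField":
        """Represent a world affine exactly as a displacement field on ``grid``."""
        x = grid.world_coords()
        disp = affine.apply(x) - x
        return DisplacementField(grid, np.moveaxis(disp, 0, -1))
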