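"""Desk-scale multimodal nonlinear registration.

Cost structure: weighted sum of per-channel data terms (mean squared
intensity difference for scalar channels, mean squared Frobenius norm of the
tensor difference after reorientation for the tensor channel) plus a bending
energy on the displacement, optimised coarse-to-fine on a trilinear knot
grid with gradient descent and a backtracking line search.

The estimated warp is the *nonlinear part only*: the subject is always
sampled through ``init`` (the affine from the affine stage), i.e. at
``A(x + d(x))``, and ``d`` is returned on the template grid.

Tensor reorientation inside the cost uses the finite-strain rotation of the
current warp, refreshed at the start of every level.  Because the Frobenius
norm is rotation-invariant, ``|R S R^T - T|`` is evaluated as
``|S - R^T T R|`` with the template rotated once per level, which keeps the
inner loop free of per-voxel matrix products.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse

from .volgeom import (
    AffineTransform,
    DisplacementField,
    ImageGrid,
    WeightImage,
    components_to_matrices,
    matrices_to_components,
)
from .volgeom.warp import jacobian_matrices

__all__ = [
    "RegLevel",
    "RegParams",
    "RegResult",
    "channel_costs",
    "rescale_channel_costs",
    "register_multimodal",
    "FileWarpBackend",
    "default_schedule",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# multiplicity of the 6 unique tensor components in the Frobenius norm
_FROB_MULT = np.array([1.0, 2.0, 2.0, 1.0, 2.0, 1.0])

SCALAR_CHANNELS = ("t1", "flair")
CHANNELS = ("t1", "flair", "dti")


@dataclass(frozen=True)
class RegLevel:
    knot_spacing: float  # mm
    fwhm: float          # mm, Gaussian blurring of both images
    iterations: int      # descent iterations at this level


def default_schedule(finest_spacing: float = 8.0,
                     coarsest_spacing: float = 32.0,
                     coarsest_fwhm: float = 8.0,
                     iterations: int = 12) -> list[RegLevel]:
    """Coarse-to-fine schedule: spacing and FWHM halved per level.

    The full-scale reference schedule runs 32 mm / 8 mm FWHM down to
    1 mm / 0.25 mm over six levels; the desk-scale default truncates at
    ``finest_spacing`` (8 mm at 48^3 x 3 mm).
    """
    levels = []
    spacing, fwhm = coarsest_spacing, coarsest_fwhm
    while spacing >= finest_spacing - 1e-9:
        levels.append(RegLevel(spacing, fwhm, iterations))
        spacing /= 2.0
        fwhm /= 2.0
    if not levels:
        raise ValueError("empty schedule")
    return levels


@dataclass
class RegParams:
    lambda_t1: float = 1.0
    lambda_flair: float = 1.0
    lambda_dti: float = 1.0
    lambda_reg: float = 1.0
    schedule: list[RegLevel] = field(default_factory=default_schedule)
    weight_masks: dict[str, WeightImage] | None = None  # template-space, per channel
    step_fraction: float = 0.4  # initial line-search step, fraction of knot spacing
    cost_multiplier: float = 1.0  # global factor; must not change the trajectory

    def __post_init__(self) -> None:
        if self.lambda_t1 <= 0 and self.lambda_flair <= 0 and self.lambda_dti <= 0:
            raise ValueError("at least one channel weight must be > 0")
        if any(l < 0 for l in (self.lambda_t1, self.lambda_flair,
                               self.lambda_dti, self.lambda_reg)):
            raise ValueError("channel weights must be nonnegative")
        spacings = [lev.knot_spacing for lev in self.schedule]
        if any(s2 >= s1 for s1, s2 in zip(spacings, spacings[1:])):
            raise ValueError("knot spacings must be strictly decreasing")

    @property
    def lambdas(self) -> dict[str, float]:
        return {"t1": self.lambda_t1, "flair": self.lambda_flair,
                "dti": self.lambda_dti}


@dataclass
class RegResult:
    warp: DisplacementField          # template -> subject, nonlinear part only
    final_costs: dict[str, float]    # unscaled per-channel data costs + "reg"
    trace: list[dict]                # per-iteration records (level, total cost, ...)


def rescale_channel_costs(costs: dict[str, float],
                          previous_scales: dict[str, float] | None = None
                          ) -> dict[str, float]:
    """Per-channel scale factors making scaled costs equal (to 1) at the
    current iterate, so the lambda weights act comparably across modalities.

    A zero-cost channel keeps its previous scale (or 1 if none).
    """
    scales = {}
    for ch, c in costs.items():
        if c > 0:
            scales[ch] = 1.0 / c
        elif previous_scales and ch in previous_scales:
            scales[ch] = previous_scales[ch]
        else:
            scales[ch] = 1.0
    return scales


def _world_gradient(values: np.ndarray, grid: ImageGrid) -> np.ndarray:
    """(*shape, 3) gradient in world (mm) units."""
    g = np.stack(np.gradient(values, edge_order=1), axis=-1)
    return g @ grid.world_to_voxel[:3, :3]


def _finite_strain_rotations(F: np.ndarray) -> np.ndarray:
    """Rotation part of (...,3,3) matrices via polar decomposition."""
    U, _, Vt = np.linalg.svd(F)
    R = U @ Vt
    neg = np.linalg.det(R) < 0
    if np.any(neg):
        U = U.copy()
        U[neg, :, -1] *= -1
        R = U @ Vt
    return R


def _reorientation_field(warp: DisplacementField, init: AffineTransform) -> np.ndarray:
    """(V,3,3) finite-strain rotations pulling subject tensors into the
    template frame: rotation part of the inverse Jacobian of init o phi."""
    J = init.linear[None, :, :] @ jacobian_matrices(warp).reshape(-1, 3, 3)
    ok = np.abs(np.linalg.det(J)) > 1e-12
    F = np.broadcast_to(np.eye(3), J.shape).copy()
    F[ok] = np.linalg.inv(J[ok])
    return _finite_strain_rotations(F)


def _rotate_components(comp: np.ndarray, rot: np.ndarray) -> np.ndarray:
    """Apply (V,3,3) rotations to (V,6) symmetric-tensor components."""
    mats = components_to_matrices(comp)
    out = np.einsum("vij,vjk,vlk->vil", rot, mats, rot)
    return matrices_to_components(out)


class _PaddedSampler:
    """Multi-channel trilinear sampling with zero fill outside the volume.

    The volume is zero-padded by one voxel so boundary-crossing points blend
    to zero exactly as scipy's constant mode; points far outside clamp into
    the zero pad.  One coordinate computation is shared by all channels.
    """

    def __init__(self, vols: np.ndarray, grid: ImageGrid):
        self.grid = grid
        self.padded = np.pad(vols.astype(np.float32),
                             ((1, 1), (1, 1), (1, 1), (0, 0)))
        self.pshape = self.padded.shape[:3]
        self.flat = self.padded.reshape(-1, self.padded.shape[3])
        self.strides = (self.pshape[1] * self.pshape[2], self.pshape[2], 1)

    def sample_world(self, pts_world: np.ndarray) -> np.ndarray:
        """(3, V) world points -> (V, C) interpolated values."""
        u = self.grid.world_to_voxel_coords(pts_world) + 1.0
        for ax in range(3):
            np.clip(u[ax], 0.0, self.pshape[ax] - 1.0, out=u[ax])
        base = u.astype(np.int64)
        for ax in range(3):
            np.minimum(base[ax], self.pshape[ax] - 2, out=base[ax])
        f = u - base
        sx, sy, _ = self.strides
        i0 = base[0] * sx + base[1] * sy + base[2]
        wx1, wy1, wz1 = f
        wx0, wy0, wz0 = 1.0 - f
        flat = self.flat
        out = (wx0 * wy0 * wz0)[:, None] * flat[i0]
        out += (wx0 * wy0 * wz1)[:, None] * flat[i0 + 1]
        out += (wx0 * wy1 * wz0)[:, None] * flat[i0 + sy]
        out += (wx0 * wy1 * wz1)[:, None] * flat[i0 + sy + 1]
        out += (wx1 * wy0 * wz0)[:, None] * flat[i0 + sx]
        out += (wx1 * wy0 * wz1)[:, None] * flat[i0 + sx + 1]
        out += (wx1 * wy1 * wz0)[:, None] * flat[i0 + sx + sy]
        out += (wx1 * wy1 * wz1)[:, None] * flat[i0 + sx + sy + 1]
        return out


class _KnotGrid:
    """Trilinear displacement parameterisation on a regular knot lattice."""

    def __init__(self, grid: ImageGrid, spacing_mm: float):
        self.grid = grid
        self.spacing = float(spacing_mm)
        fov = np.array(grid.shape) * grid.voxel_sizes
        self.shape = tuple(int(np.ceil(f / self.spacing)) + 3 for f in fov)
        vox = grid.voxel_coords().reshape(3, -1)
        mm = vox * grid.voxel_sizes[:, None]
        u = mm / self.spacing + 1.0  # knot k at (k - 1) * spacing per axis
        base = np.floor(u).astype(np.int64)
        frac = u - base
        for ax, n in enumerate(self.shape):
            np.clip(base[ax], 0, n - 2, out=base[ax])
        w, idx = [], []
        strides = np.array([self.shape[1] * self.shape[2], self.shape[2], 1])
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    wx = frac[0] if dx else 1 - frac[0]
                    wy = frac[1] if dy else 1 - frac[1]
                    wz = frac[2] if dz else 1 - frac[2]
                    w.append(wx * wy * wz)
                    idx.append((base[0] + dx) * strides[0]
                               + (base[1] + dy) * strides[1] + (base[2] + dz))
        weights = np.stack(w)     # (8, V)
        indices = np.stack(idx)   # (8, V)
        self.n_knots = int(np.prod(self.shape))
        nvox = weights.shape[1]
        rows = np.tile(np.arange(nvox), 8)
        self._P = sparse.csr_matrix(
            (weights.ravel(), (rows, indices.ravel())),
            shape=(nvox, self.n_knots))
        self._PT = self._P.T.tocsr()

    def to_dense(self, coeffs: np.ndarray) -> np.ndarray:
        """(K1,K2,K3,3) knot coefficients -> (V,3) dense displacement."""
        return self._P @ coeffs.reshape(-1, 3)

    def dense_adjoint(self, dense_grad: np.ndarray) -> np.ndarray:
        """Adjoint of to_dense: (V,3) voxel gradient -> knot gradient."""
        return (self._PT @ dense_grad).reshape(self.shape + (3,))

    def fit(self, dense: np.ndarray) -> np.ndarray:
        """Initialise knot coefficients from a dense (V,3) field by sampling
        the field at knot positions (edge-clamped)."""
        d = dense.reshape(self.grid.shape + (3,))
        knot_mm = np.meshgrid(*(np.arange(n, dtype=float) - 1.0 for n in self.shape),
                              indexing="ij")
        coeffs = np.empty(self.shape + (3,))
        vox = np.stack([
            (knot_mm[ax] * self.spacing / self.grid.voxel_sizes[ax]).reshape(-1)
            for ax in range(3)
        ])
        for c in range(3):
            coeffs[..., c] = ndimage.map_coordinates(
                d[..., c], vox, order=1, mode="nearest").reshape(self.shape)
        return coeffs

    def bending_energy(self, coeffs: np.ndarray, with_grad: bool = True):
        """Mean squared second derivatives over the knot lattice."""
        h2 = self.spacing ** 2
        energy = 0.0
        grad = np.zeros_like(coeffs) if with_grad else None
        second = np.array([1.0, -2.0, 1.0]) / h2
        first = np.array([0.5, 0.0, -0.5]) / self.spacing
        n = coeffs[..., 0].size
        for c in range(3):
            f = coeffs[..., c]
            for ax in range(3):
                d2 = ndimage.correlate1d(f, second, axis=ax, mode="constant")
                energy += float(np.sum(d2 * d2)) / n
                if with_grad:
                    grad[..., c] += 2.0 / n * ndimage.correlate1d(
                        d2, second, axis=ax, mode="constant")
            for ax1, ax2 in ((0, 1), (0, 2), (1, 2)):
                d11 = ndimage.correlate1d(f, first, axis=ax1, mode="constant")
                dxy = ndimage.correlate1d(d11, first, axis=ax2, mode="constant")
                energy += 2.0 * float(np.sum(dxy * dxy)) / n
                if with_grad:
                    # first-difference kernel is antisymmetric: adjoint == correlate
                    # applied twice restores the sign
                    back = ndimage.correlate1d(dxy, first, axis=ax2, mode="constant")
                    back = ndimage.correlate1d(back, first, axis=ax1, mode="constant")
                    grad[..., c] += 4.0 / n * back
        return (energy, grad) if with_grad else (energy, None)


def _smooth(vals: np.ndarray, grid: ImageGrid, fwhm: float) -> np.ndarray:
    if fwhm <= 0:
        return vals
    sigma = fwhm * FWHM_TO_SIGMA / grid.voxel_sizes
    return ndimage.gaussian_filter(vals, sigma=sigma)


#: channel slices into the packed 8-component subject/template arrays
_SLICES = {"t1": slice(0, 1), "flair": slice(1, 2), "dti": slice(2, 8)}
_MULT = np.concatenate([[1.0], [1.0], _FROB_MULT])


class _LevelData:
    """Smoothed, packed subject and template data for one level."""

    def __init__(self, subject, template, grid: ImageGrid, fwhm: float):
        sgrid = subject.t1.grid
        subj = np.stack(
            [_smooth(subject.t1.values, sgrid, fwhm),
             _smooth(subject.flair.values, sgrid, fwhm)]
            + [_smooth(subject.dti.components[..., c], sgrid, fwhm)
               for c in range(6)],
            axis=-1,
        )
        self.sampler = _PaddedSampler(subj, sgrid)
        grads = np.stack(
            [_world_gradient(subj[..., c], sgrid) for c in range(8)], axis=-2
        ).reshape(sgrid.shape + (24,))
        self.grad_sampler = _PaddedSampler(grads, sgrid)
        self.template = np.stack(
            [_smooth(template.t1.values, grid, fwhm).reshape(-1),
             _smooth(template.flair.values, grid, fwhm).reshape(-1)]
            + [_smooth(template.dti.components[..., c], grid, fwhm).reshape(-1)
               for c in range(6)],
            axis=-1,
        )

    def rotated_template(self, rot: np.ndarray) -> np.ndarray:
        """Template with DTI conjugated by rot^T (Frobenius-equivalent to
        rotating the sampled subject tensors by rot)."""
        out = self.template.copy()
        out[:, 2:8] = _rotate_components(
            self.template[:, 2:8], np.swapaxes(rot, -1, -2))
        return out


def _pack_weights(weights: dict[str, np.ndarray]) -> np.ndarray:
    """(V, 8) per-voxel, per-component weights including Frobenius multiplicity."""
    w = np.empty((weights["t1"].size, 8))
    w[:, 0] = weights["t1"]
    w[:, 1] = weights["flair"]
    w[:, 2:8] = weights["dti"][:, None] * _FROB_MULT[None, :]
    return w


def _resolve_weights(weight_masks, grid: ImageGrid) -> dict[str, np.ndarray]:
    out = {}
    for name in CHANNELS:
        if weight_masks and name in weight_masks and weight_masks[name] is not None:
            out[name] = weight_masks[name].weights.reshape(-1)
        else:
            out[name] = np.ones(int(np.prod(grid.shape)))
    return out


def channel_costs(subject, template, warp: DisplacementField,
                  weight_masks: dict[str, WeightImage] | None = None,
                  init: AffineTransform | None = None) -> dict[str, float]:
    """Unscaled per-channel data costs of ``warp`` plus the bending energy.

    Scalar channels: weighted mean squared intensity difference; tensor
    channel: weighted mean squared Frobenius norm of the tensor difference
    after finite-strain reorientation; "reg": bending energy of the
    displacement on a knot lattice at twice the voxel scale.
    """
    init = init or AffineTransform.identity()
    grid = warp.grid
    weights = _resolve_weights(weight_masks, grid)
    if all(w.sum() == 0 for w in weights.values()):
        raise ValueError("all-zero weight masks")
    data = _LevelData(subject, template, grid, fwhm=0.0)
    rot = _reorientation_field(warp, init)
    tmpl = data.rotated_template(rot)
    pts = init.apply(warp.positions()).reshape(3, -1)
    sampled = data.sampler.sample_world(pts)
    resid2 = (sampled - tmpl) ** 2
    costs = {}
    for name in CHANNELS:
        sl = _SLICES[name]
        w = weights[name]
        costs[name] = float(
            (w[:, None] * resid2[:, sl] * _MULT[sl][None, :]).sum() / w.sum())
    kg = _KnotGrid(grid, float(np.min(grid.voxel_sizes)) * 2.0)
    costs["reg"] = kg.bending_energy(kg.fit(warp.disp.reshape(-1, 3)),
                                     with_grad=False)[0]
    return costs


def register_multimodal(subject, template, params: RegParams,
                        init: AffineTransform | None = None) -> RegResult:
    """Multiresolution descent on the total cost; returns the nonlinear warp
    on the template grid (``init`` excluded), per-channel final costs and the
    convergence trace."""
    init = init or AffineTransform.identity()
    grid: ImageGrid = template.t1.grid
    weights = _resolve_weights(params.weight_masks, grid)
    lambdas = params.lambdas
    x_world = grid.world_coords().reshape(3, -1)
    wsums = {name: weights[name].sum() for name in CHANNELS}
    if all(s == 0 for s in wsums.values()):
        raise ValueError("all-zero weight masks")

    dense = np.zeros((x_world.shape[1], 3))
    trace: list[dict] = []
    scales: dict[str, float] = {}
    gamma = params.cost_multiplier

    for level_idx, level in enumerate(params.schedule):
        data = _LevelData(subject, template, grid, level.fwhm)
        kg = _KnotGrid(grid, level.knot_spacing)
        coeffs = kg.fit(dense)
        dense = kg.to_dense(coeffs)

        # reorientation refreshed from the current warp at each level
        rot = _reorientation_field(
            DisplacementField(grid, dense.reshape(grid.shape + (3,))), init)
        tmpl = data.rotated_template(rot)

        def evaluate(coeffs, with_grad):
            d = kg.to_dense(coeffs)
            pts = init.apply(x_world + d.T)
            sampled = data.sampler.sample_world(pts)
            resid = sampled - tmpl
            raw = {}
            total = 0.0
            for name in CHANNELS:
                sl = _SLICES[name]
                w = weights[name]
                c = float((w[:, None] * resid[:, sl] ** 2
                           * _MULT[sl][None, :]).sum() / wsums[name])
                raw[name] = c
                total += lambdas[name] * scales.get(name, 1.0) * c
            be, be_grad = kg.bending_energy(coeffs, with_grad=with_grad)
            raw["reg"] = be
            total += params.lambda_reg * be
            if not np.isfinite(total):
                raise FloatingPointError(
                    f"non-finite cost at level {level_idx} ({raw})")
            if not with_grad:
                return gamma * total, raw, None
            grads = data.grad_sampler.sample_world(pts).reshape(-1, 8, 3)
            coeff = np.empty_like(resid)
            for name in CHANNELS:
                sl = _SLICES[name]
                coeff[:, sl] = (2.0 * lambdas[name] * scales.get(name, 1.0)
                                / wsums[name]) * weights[name][:, None] \
                    * resid[:, sl] * _MULT[sl][None, :]
            gvox = np.einsum("vc,vcx->vx", coeff, grads) @ init.linear
            knot_grad = kg.dense_adjoint(gvox)
            knot_grad += params.lambda_reg * be_grad
            return gamma * total, raw, gamma * knot_grad

        # freeze the per-channel rescaling at the level's starting costs
        _, raw0, _ = evaluate(coeffs, with_grad=False)
        scales = rescale_channel_costs(
            {k: v for k, v in raw0.items() if k != "reg"}, scales)

        step0 = params.step_fraction * level.knot_spacing
        alpha_prev = None
        for it in range(level.iterations):
            f0, raw, g = evaluate(coeffs, with_grad=True)
            gmax = float(np.max(np.abs(g)))
            record = {"level": level_idx, "iteration": it, "total": f0,
                      **{f"cost_{k}": v for k, v in raw.items()}}
            if gmax == 0:
                trace.append(record)
                break
            alpha = step0 / gmax
            if alpha_prev is not None:
                alpha = min(alpha, 2.0 * alpha_prev)
            gnorm2 = float(np.sum(g * g))
            accepted = False
            for _ in range(12):
                trial = coeffs - alpha * g
                f1, raw1, _ = evaluate(trial, with_grad=False)
                if f1 <= f0 - 1e-4 * alpha * gnorm2:
                    coeffs = trial
                    accepted = True
                    alpha_prev = alpha
                    break
                alpha *= 0.5
            if accepted:
                record.update(total=f1, step=alpha,
                              **{f"cost_{k}": v for k, v in raw1.items()})
            trace.append(record)
            if not accepted:
                break
        dense = kg.to_dense(coeffs)

    warp = DisplacementField(grid, dense.reshape(grid.shape + (3,)))
    final = channel_costs(subject, template, warp,
                          weight_masks=params.weight_masks, init=init)
    return RegResult(warp=warp, final_costs=final, trace=trace)


class FileWarpBackend:
    """Registration backend that imports pre-computed warps from NIfTI files.

    ``path_for(subject_id)`` must return the path of a displacement field on
    the template grid (nonlinear part only, the same contract as
    :func:`register_multimodal`).
    """

    def __init__(self, path_for):
        self.path_for = path_for

    def __call__(self, subject, template, params: RegParams,
                 init: AffineTransform | None = None) -> RegResult:
        from .volgeom import load_displacement

        warp = load_displacement(self.path_for(subject.id))
        if not warp.grid.same_as(template.t1.grid):
            raise ValueError(
                f"imported warp grid for {subject.id} does not match template grid")
        costs = channel_costs(subject, template, warp,
                              weight_masks=params.weight_masks, init=init)
        return RegResult(warp=warp, final_costs=costs, trace=[])
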