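"""Affine alignment stage: pairwise registration, unbiased midspace,
median affine template, and the mask/weight recipes.

Affine transforms here are *pullback* resampling maps: a subject's transform
maps template-space world coordinates to that subject's native coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy import ndimage, optimize

from .volgeom import (
    AffineTransform,
    ScalarImage,
    WeightImage,
    log_euclidean_mean_images,
    resample_scalar,
    resample_tensor,
    voxelwise_median,
)

__all__ = [
    "AffineSet",
    "RegistrationDivergence",
    "affine_register",
    "midspace_transforms",
    "build_affine_template",
    "make_weight_mask",
    "make_dti_soft_mask",
    "clamp_scalp_intensities",
]


class RegistrationDivergence(RuntimeError):
    pass


@dataclass
class AffineSet:
    """Per-subject pullback affines (template space -> subject native space)."""

    transforms: dict[str, AffineTransform]
    reference_id: str

    def __post_init__(self) -> None:
        for sid, t in self.transforms.items():
            if abs(np.linalg.det(t.matrix)) < 1e-12:
                raise ValueError(f"transform for {sid} is not invertible")


def _params_to_affine(params: np.ndarray, center: np.ndarray, dof: str) -> AffineTransform:
    t = params[0:3]
    rx, ry, rz = params[3:6]
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    R = (np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
         @ np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
         @ np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]]))
    if dof == "affine12":
        scales = np.exp(params[6:9])
        hxy, hxz, hyz = params[9:12]
        Sh = np.array([[1, hxy, hxz], [0, 1, hyz], [0, 0, 1]])
        lin = R @ Sh @ np.diag(scales)
    else:
        lin = R
    mat = np.eye(4)
    mat[:3, :3] = lin
    mat[:3, 3] = t + center - lin @ center
    return AffineTransform(mat, dof)


def affine_register(moving: ScalarImage, fixed: ScalarImage, dof: str = "affine12",
                    levels: tuple[float, ...] = (3.0, 1.5, 0.0),
                    maxiter: int = 60) -> AffineTransform:
    """Estimate the pullback affine A minimising MSE(fixed(x), moving(A(x))).

    Multiresolution: both images are smoothed with a Gaussian pyramid
    (``levels`` are sigmas in voxels) and Powell's derivative-free method
    refines the parameters at each level.  Deterministic given inputs.
    """
    if dof not in ("rigid6", "affine12"):
        raise ValueError(f"dof must be rigid6 or affine12, got {dof!r}")
    nparams = 6 if dof == "rigid6" else 12
    grid = fixed.grid
    center = grid.voxel_to_world[:3, :3] @ ((np.array(grid.shape) - 1) / 2.0) \
        + grid.voxel_to_world[:3, 3]
    x_all = grid.world_coords()

    # parameter scaling so Powell's unit steps are comparable across kinds
    scales = np.concatenate([
        np.full(3, 1.0),        # mm
        np.full(3, np.pi / 180),  # ~1 degree
        np.full(3, 0.01) if nparams == 12 else np.empty(0),
        np.full(3, 0.01) if nparams == 12 else np.empty(0),
    ])

    params = np.zeros(nparams)
    for sigma in levels:
        if sigma > 0:
            fix = ndimage.gaussian_filter(fixed.values, sigma)
            mov = ndimage.gaussian_filter(moving.values, sigma)
        else:
            fix, mov = fixed.values, moving.values
        # smoothed levels are evaluated on a strided voxel subset
        stride = 2 if sigma >= 1.5 else 1
        sl = (slice(None, None, stride),) * 3
        fix_flat = fix[sl].reshape(-1)
        x_world = x_all[(slice(None),) + sl].reshape(3, -1)

        def cost(p):
            aff = _params_to_affine(p * scales, center, dof)
            vox = moving.grid.world_to_voxel_coords(aff.apply(x_world))
            sampled = ndimage.map_coordinates(mov, vox, order=1,
                                              mode="constant", cval=0.0)
            return float(np.mean((fix_flat - sampled) ** 2))

        level_start = cost(params)
        res = optimize.minimize(cost, params, method="Powell",
                                options={"maxiter": maxiter, "xtol": 1e-4,
                                         "ftol": 1e-7})
        # costs are only comparable within one smoothing level
        if res.fun > level_start * (1 + 1e-9):
            raise RegistrationDivergence(
                f"affine registration diverged at sigma={sigma}: "
                f"cost {level_start:.4g} -> {res.fun:.4g}")
        params = res.x
    return _params_to_affine(params * scales, center, dof)


def _real_logm(mat: np.ndarray, name: str) -> np.ndarray:
    evals = np.linalg.eigvals(mat)
    if np.any((evals.real < 0) & (np.abs(evals.imag) < 1e-12)):
        raise ValueError(f"matrix log undefined (negative real eigenvalue) for {name}")
    log = sla.logm(mat)
    if np.max(np.abs(log.imag)) > 1e-8:
        raise ValueError(f"matrix log not real for {name}")
    return log.real


def midspace_transforms(affines: AffineSet, tol: float = 1e-9,
                        max_iter: int = 100) -> AffineSet:
    """Re-center a set of affines on their matrix-logarithm mean.

    Returns per-subject transforms to an unbiased midspace: the output set
    B_n = M^-1 A_n, with M iterated (Karcher-style) until the mean matrix
    log of the outputs is identity to within ``tol``.
    """
    if len(affines.transforms) < 2:
        raise ValueError("midspace requires at least 2 subjects")
    ids = list(affines.transforms)
    mats = {sid: affines.transforms[sid].matrix for sid in ids}
    M = np.eye(4)
    for _ in range(max_iter):
        Minv = np.linalg.inv(M)
        L = np.mean([_real_logm(Minv @ mats[sid], sid) for sid in ids], axis=0)
        if np.linalg.norm(L, "fro") < tol:
            break
        M = M @ sla.expm(L)
    out = {
        sid: AffineTransform(np.linalg.inv(M) @ mats[sid],
                             affines.transforms[sid].dof_tag)
        for sid in ids
    }
    return AffineSet(out, affines.reference_id)


def make_weight_mask(soft_brain_mask: WeightImage) -> WeightImage:
    """Threshold at 0.1, binarise, multiply by 7, add 1, rescale to mean 1.

    The intra-to-extracranial weight ratio is 8:1 by construction and the
    whole-volume mean is exactly 1.
    """
    soft = soft_brain_mask.weights
    if soft.min() < 0 or soft.max() > 1 + 1e-9:
        raise ValueError("soft mask must be in [0, 1]")
    binary = (soft > 0.1).astype(float)
    if binary.sum() == 0:
        raise ValueError("mask is empty after thresholding at 0.1")
    w = binary * 7.0 + 1.0
    w /= w.mean()
    return WeightImage(soft_brain_mask.grid, w, mean_normalised=True)


def make_dti_soft_mask(binary_mask: ScalarImage, filter_mode: str = "mean") -> WeightImage:
    """Shrink a binary mask: 3x3x3 box filter, threshold at 0.9, erode by one voxel.

    ``filter_mode='mean'`` normalises the box filter by 27 so the 0.9
    threshold acts on a [0, 1] scale (default); ``'sum'`` applies the filter
    un-normalised, matching the literal reading.
    """
    vals = binary_mask.values
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValueError("input must be binary")
    box = ndimage.uniform_filter(vals, size=3, mode="constant", cval=0.0)
    if filter_mode == "sum":
        box = box * 27.0
    elif filter_mode != "mean":
        raise ValueError(f"filter_mode must be 'mean' or 'sum', got {filter_mode!r}")
    thresh = (box >= 0.9).astype(float)
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    eroded = ndimage.binary_erosion(thresh, structure=structure).astype(float)
    return WeightImage(binary_mask.grid, eroded)


def clamp_scalp_intensities(t1: ScalarImage, brain_mask: ScalarImage,
                            percentile: float = 99.0,
                            softness: float = 0.2) -> ScalarImage:
    """Smoothly compress bright extracranial intensities.

    Outside-brain values above the given percentile of the outside-brain
    distribution are mapped through a tanh tail: continuous, differentiable,
    strictly monotone, bounded by threshold + softness * (max - threshold).
    In-brain values are untouched.
    """
    if not 50.0 < percentile < 100.0:
        raise ValueError("percentile must be in (50, 100)")
    outside = brain_mask.values < 0.5
    vals = t1.values.copy()
    out_vals = vals[outside]
    if out_vals.size == 0:
        return ScalarImage(t1.grid, vals)
    thr = float(np.percentile(out_vals, percentile))
    vmax = float(out_vals.max())
    span = softness * (vmax - thr)
    if span <= 0:
        return ScalarImage(t1.grid, vals)
    above = outside & (t1.values > thr)
    vals[above] = thr + span * np.tanh((t1.values[above] - thr) / span)
    return ScalarImage(t1.grid, vals)


def build_affine_template(cohort, seed_subject: int = 0,
                          reference: ScalarImage | None = None,
                          dof: str = "affine12"):
    """Unbiased affine template: pairwise registration to a seed subject,
    log-mean midspace unbiasing, voxel-wise median of scalars, log-Euclidean
    tensor mean, soft masks from trilinearly resampled binary masks.

    If ``reference`` is given, the median template is additionally rigidly
    (6-DOF) aligned to it and the rigid factor folded into every subject's
    transform.  Returns (MultimodalTemplate, AffineSet).
    """
    from .template_builder import MultimodalTemplate, normalize_intensity

    subjects = cohort.subjects
    if not subjects:
        raise ValueError("cohort is empty")
    seed = subjects[seed_subject]
    grid = seed.t1.grid

    transforms: dict[str, AffineTransform] = {}
    for sub in subjects:
        if sub.id == seed.id:
            transforms[sub.id] = AffineTransform(np.eye(4), dof)
            continue
        try:
            transforms[sub.id] = affine_register(sub.t1, seed.t1, dof=dof)
        except RegistrationDivergence as exc:
            raise RegistrationDivergence(f"subject {sub.id}: {exc}") from exc

    affines = midspace_transforms(AffineSet(transforms, seed.id))

    if reference is not None:
        t1_mid = voxelwise_median([
            resample_scalar(sub.t1, affines.transforms[sub.id], order=3, out_grid=grid)
            for sub in subjects
        ])
        # rigid pullback reference-space -> midspace; moving is the template
        rigid = affine_register(t1_mid, reference, dof="rigid6")
        grid = reference.grid
        affines = AffineSet(
            {sid: t.compose(rigid) for sid, t in affines.transforms.items()},
            affines.reference_id,
        )

    t1s, flairs, dtis, t1_masks, dti_masks = [], [], [], [], []
    for sub in subjects:
        aff = affines.transforms[sub.id]
        t1s.append(resample_scalar(sub.t1, aff, order=3, out_grid=grid))
        flairs.append(resample_scalar(sub.flair, aff, order=3, out_grid=grid))
        dtis.append(resample_tensor(sub.dti, aff, out_grid=grid))
        t1_masks.append(resample_scalar(sub.brain_mask, aff, order=1, out_grid=grid))
        eroded = make_dti_soft_mask(sub.brain_mask)
        dti_masks.append(resample_scalar(
            ScalarImage(sub.brain_mask.grid, eroded.weights), aff, order=1,
            out_grid=grid))

    t1_med = normalize_intensity(voxelwise_median(t1s), "auto")
    flair_med = normalize_intensity(voxelwise_median(flairs), "auto")
    dti_mean = log_euclidean_mean_images(dtis)
    soft_t1 = WeightImage(grid, np.clip(
        np.mean([m.values for m in t1_masks], axis=0), 0.0, 1.0))
    soft_dti = WeightImage(grid, np.clip(
        np.mean([m.values for m in dti_masks], axis=0), 0.0, 1.0))

    template = MultimodalTemplate(
        t1=t1_med, flair=flair_med, dti=dti_mean,
        soft_t1_mask=soft_t1, soft_dti_mask=soft_dti,
        iteration=0, provenance={"stage": "affine", "n_subjects": len(subjects)},
    )
    return template, affines
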