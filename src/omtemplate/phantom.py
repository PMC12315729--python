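"""Synthetic multimodal brain phantoms with known ground-truth deformations.

A deterministic canonical head (scalp shell, skull gap, GM shell, WM
interior, mirrored ellipsoidal ventricles, a C-shaped anisotropic tract) is
evaluated analytically at arbitrary world points.  Subjects are produced by
composing an age-dependent ventricle expansion, a smooth random warp and a
small random affine into a forward map ``phi`` (canonical -> subject
coordinates).  The stored truth field lives on the canonical grid and maps
canonical points to subject points, i.e. it is exactly the pullback warp that
resamples the subject back into canonical space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volgeom import (
    AffineTransform,
    DisplacementField,
    ImageGrid,
    ScalarImage,
    TensorImage,
    jacobian_determinant_map,
    jacobian_matrices,
    invert_warp,
    matrices_to_components,
    ppd_rotation,
    sample_displacement,
)

__all__ = [
    "PhantomParams",
    "SyntheticSubject",
    "SyntheticCohort",
    "make_canonical_anatomy",
    "make_subject",
    "make_cohort",
    "canonical_ventricle_mask",
    "tract_centerline_points",
]

# nominal anatomy, mm, for a 144 mm field of view; scaled to the actual FOV
_NOMINAL_FOV = 144.0
_SCALP_RADII = (52.0, 60.0, 50.0)
_SKULL_GAP = 6.0          # scalp shell thickness
_BRAIN_OFFSET = 12.0      # scalp outer -> brain (GM) outer
_WM_OFFSET = 20.0         # scalp outer -> WM outer
_VENT_CENTER = (12.0, 6.0, 2.0)   # mirrored in x
_VENT_RADII = (6.0, 12.0, 7.0)
_TRACT_RADIUS = 23.0      # C-arc radius in the x-z plane
_TRACT_TUBE = 5.0         # tube radius
_TRACT_ARC = (-150.0, 150.0)  # arc extent, degrees

# intensities: (scalp, skull, GM, WM, ventricle)
_T1_LEVELS = (850.0, 150.0, 600.0, 800.0, 180.0)
_FLAIR_LEVELS = (300.0, 100.0, 700.0, 500.0, 120.0)

# diffusivities, mm^2/s
_ISO_DIFF = 0.7e-3
_CSF_DIFF = 2.8e-3
_TRACT_AXIAL = 1.7e-3
_TRACT_RADIAL = 0.4e-3


@dataclass(frozen=True)
class PhantomParams:
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size: float = 3.0
    ventricle_age_slope: float = 0.004   # fractional radius growth per year
    reference_age: float = 52.5
    subject_warp_amplitude: float = 2.5  # mm, 95th percentile of |d|
    subject_warp_smoothness: float = 12.0  # mm, Gaussian sigma
    affine_jitter: tuple[float, float] = (3.0, 0.02)  # max rot deg, max scale dev
    affine_translation: float = 2.0      # mm, max per-axis translation
    noise_sd: tuple[float, float, float] = (8.0, 8.0, 2e-5)  # t1, flair, dti comps
    edge_softness: float = 3.0           # mm, smoothstep width of tissue edges

    def __post_init__(self) -> None:
        if self.subject_warp_amplitude < 0 or self.subject_warp_smoothness <= 0:
            raise ValueError("warp amplitude must be >= 0 and smoothness > 0")
        if any(j < 0 for j in self.affine_jitter) or self.affine_translation < 0:
            raise ValueError("affine jitter must be nonnegative")
        # head must fit with >= 2 voxels of margin on every side
        fov = min(s * self.voxel_size for s in self.grid_shape)
        scale = fov / _NOMINAL_FOV
        margin = fov / 2 - max(_SCALP_RADII) * scale
        if margin < 2 * self.voxel_size:
            raise ValueError(
                f"phantom head does not fit the grid with a 2-voxel margin "
                f"(margin {margin:.1f} mm, need {2 * self.voxel_size:.1f} mm)"
            )

    @property
    def grid(self) -> ImageGrid:
        return ImageGrid.isotropic(self.grid_shape, self.voxel_size)

    @property
    def anatomy_scale(self) -> float:
        return min(s * self.voxel_size for s in self.grid_shape) / _NOMINAL_FOV

    @property
    def center(self) -> np.ndarray:
        g = self.grid
        return g.voxel_to_world[:3, :3] @ ((np.array(g.shape) - 1) / 2.0) \
            + g.voxel_to_world[:3, 3]


@dataclass
class SyntheticSubject:
    id: str
    age: float
    t1: ScalarImage
    flair: ScalarImage
    dti: TensorImage
    brain_mask: ScalarImage
    truth_warp_to_canonical: DisplacementField
    truth_affine: AffineTransform


@dataclass
class SyntheticCohort:
    subjects: list[SyntheticSubject]
    params: PhantomParams

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(ids) != len(set(ids)):
            raise ValueError("subject ids must be unique")

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.age for s in self.subjects])


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _inside(rho: np.ndarray, width: float) -> np.ndarray:
    """Smooth indicator of rho <= 1 (1 inside, 0 outside), edge width in rho units."""
    return _smoothstep((1.0 + width / 2 - rho) / max(width, 1e-12))


class _CanonicalAnatomy:
    """Analytic evaluation of the canonical head at world points (3, N)."""

    def __init__(self, params: PhantomParams):
        self.params = params
        s = params.anatomy_scale
        self.center = params.center
        self.scalp = np.array(_SCALP_RADII) * s
        self.skull = self.scalp - _SKULL_GAP * s
        self.brain = self.scalp - _BRAIN_OFFSET * s
        self.wm = self.scalp - _WM_OFFSET * s
        self.vent_centers = [
            self.center + np.array([+_VENT_CENTER[0], _VENT_CENTER[1], _VENT_CENTER[2]]) * s,
            self.center + np.array([-_VENT_CENTER[0], _VENT_CENTER[1], _VENT_CENTER[2]]) * s,
        ]
        self.vent_radii = np.array(_VENT_RADII) * s
        self.tract_radius = _TRACT_RADIUS * s
        self.tract_tube = _TRACT_TUBE * s
        self.edge = params.edge_softness * s

    def _rho(self, pts: np.ndarray, radii: np.ndarray,
             center: np.ndarray | None = None) -> np.ndarray:
        c = self.center if center is None else center
        rel = (pts - c[:, None]) / radii[:, None]
        return np.linalg.norm(rel, axis=0)

    def indicators(self, pts: np.ndarray) -> dict[str, np.ndarray]:
        e = self.edge
        ind = {
            "scalp": _inside(self._rho(pts, self.scalp), e / self.scalp.min()),
            "skull": _inside(self._rho(pts, self.skull), e / self.skull.min()),
            "brain": _inside(self._rho(pts, self.brain), e / self.brain.min()),
            "wm": _inside(self._rho(pts, self.wm), e / self.wm.min()),
        }
        vent = np.zeros(pts.shape[1])
        for c in self.vent_centers:
            vent = np.maximum(
                vent, _inside(self._rho(pts, self.vent_radii, c), e / self.vent_radii.min())
            )
        ind["vent"] = vent
        return ind

    @staticmethod
    def _compose_levels(ind: dict[str, np.ndarray], levels) -> np.ndarray:
        scalp, skull, gm, wm, vent = levels
        out = scalp * (ind["scalp"] - ind["skull"])
        out += skull * (ind["skull"] - ind["brain"])
        out += gm * (ind["brain"] - ind["wm"])
        out += wm * ind["wm"]
        out += (vent - wm) * ind["vent"] * ind["wm"]
        return out

    def t1(self, pts: np.ndarray) -> np.ndarray:
        return self._compose_levels(self.indicators(pts), _T1_LEVELS)

    def flair(self, pts: np.ndarray) -> np.ndarray:
        return self._compose_levels(self.indicators(pts), _FLAIR_LEVELS)

    def brain_mask(self, pts: np.ndarray) -> np.ndarray:
        return (self.indicators(pts)["brain"] > 0.5).astype(float)

    def tract_blend(self, pts: np.ndarray) -> np.ndarray:
        """Smooth membership of the C-shaped tract tube (within WM)."""
        rel = pts - self.center[:, None]
        r_xz = np.hypot(rel[0], rel[2])
        d_tube = np.hypot(r_xz - self.tract_radius, rel[1])
        angle = np.degrees(np.arctan2(rel[2], rel[0]))
        in_arc = _smoothstep((angle - _TRACT_ARC[0]) / 15.0) * \
            _smoothstep((_TRACT_ARC[1] - angle) / 15.0)
        tube = _smoothstep((self.tract_tube - d_tube) / self.edge + 0.5)
        return tube * in_arc

    def tract_tangent(self, pts: np.ndarray) -> np.ndarray:
        """Unit tangent of the arc (circle in the x-z plane) at each point."""
        rel = pts - self.center[:, None]
        t = np.stack([-rel[2], np.zeros(pts.shape[1]), rel[0]])
        norm = np.linalg.norm(t, axis=0)
        t /= np.where(norm > 1e-9, norm, 1.0)
        t[0, norm <= 1e-9] = 1.0
        return t

    def dti(self, pts: np.ndarray) -> np.ndarray:
        """(N, 3, 3) tensors: cigar along the tract tangent in WM, isotropic
        elsewhere in the brain, CSF-like in ventricles, zero outside."""
        ind = self.indicators(pts)
        n = pts.shape[1]
        iso_level = _ISO_DIFF * ind["brain"] + (_CSF_DIFF - _ISO_DIFF) * \
            ind["vent"] * ind["wm"]
        D = np.einsum("n,ij->nij", iso_level, np.eye(3))
        blend = self.tract_blend(pts) * ind["wm"] * (1.0 - ind["vent"])
        if np.any(blend > 0):
            t = self.tract_tangent(pts).T  # (N, 3)
            cigar = _TRACT_RADIAL * np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
            cigar += (_TRACT_AXIAL - _TRACT_RADIAL) * np.einsum("ni,nj->nij", t, t)
            b = blend[:, None, None]
            D = D * (1 - b) + cigar * b
        # fade tensors to zero with the brain indicator outside the brain
        D *= np.clip(ind["brain"], 0.0, 1.0)[:, None, None]
        D[ind["brain"] < 0.5] = 0.0
        return D


def canonical_ventricle_mask(params: PhantomParams) -> ScalarImage:
    """Binary canonical-space mask of both ventricles (strict interior)."""
    anat = _CanonicalAnatomy(params)
    pts = params.grid.world_coords().reshape(3, -1)
    vent = np.zeros(pts.shape[1], dtype=bool)
    for c in anat.vent_centers:
        vent |= anat._rho(pts, anat.vent_radii, c) <= 1.0
    return ScalarImage(params.grid, vent.reshape(params.grid_shape).astype(float))


def tract_centerline_points(params: PhantomParams, n: int = 50) -> np.ndarray:
    """(3, n) world points along the tract centerline (for oracle checks)."""
    anat = _CanonicalAnatomy(params)
    ang = np.radians(np.linspace(_TRACT_ARC[0] + 25, _TRACT_ARC[1] - 25, n))
    pts = np.stack([
        anat.center[0] + anat.tract_radius * np.cos(ang),
        np.full(n, anat.center[1]),
        anat.center[2] + anat.tract_radius * np.sin(ang),
    ])
    return pts


def _ventricle_expansion(pts: np.ndarray, anat: _CanonicalAnatomy,
                         scale: float) -> np.ndarray:
    """Forward displacement expanding both ventricles by ``scale``.

    Pure scaling about each ventricle center inside an ellipsoidal core
    (exact s^3 volume change), decaying as rho^-3 with a smooth cutoff so
    the two ventricles do not interact and the skull stays put.
    """
    disp = np.zeros_like(pts)
    if scale == 1.0:
        return disp
    core = anat.vent_radii * 1.15
    for c in anat.vent_centers:
        rel = pts - c[:, None]
        rho = np.linalg.norm(rel / core[:, None], axis=0)
        gain = np.where(rho <= 1.0, 1.0, 1.0 / np.maximum(rho, 1.0) ** 3)
        gain = gain * _smoothstep((3.0 - rho) / 1.0)
        disp += (scale - 1.0) * rel * gain
    return disp


def _random_smooth_field(params: PhantomParams, amplitude: float,
                         rng: np.random.Generator) -> DisplacementField:
    """Gaussian-filtered white noise, tapered at the grid edge, rescaled so the
    95th percentile of |d| equals ``amplitude`` mm."""
    grid = params.grid
    sigma_vox = params.subject_warp_smoothness / grid.voxel_sizes
    disp = rng.standard_normal(grid.shape + (3,))
    for c in range(3):
        disp[..., c] = ndimage.gaussian_filter(disp[..., c], sigma=sigma_vox)
    # taper to zero over the outer 3 voxels
    for ax, n in enumerate(grid.shape):
        ramp = np.minimum(np.arange(n), np.arange(n)[::-1]) / 3.0
        window = _smoothstep(ramp)
        shape = [1, 1, 1, 1]
        shape[ax] = n
        disp *= window.reshape(shape)
    mag = np.linalg.norm(disp, axis=-1)
    p95 = np.percentile(mag, 95)
    if p95 > 0 and amplitude > 0:
        disp *= amplitude / p95
    else:
        disp[:] = 0.0
    return DisplacementField(grid, disp)


def _random_affine(params: PhantomParams, rng: np.random.Generator) -> AffineTransform:
    max_rot, max_scale = params.affine_jitter
    angles = np.radians(rng.uniform(-max_rot, max_rot, size=3))
    scales = 1.0 + rng.uniform(-max_scale, max_scale, size=3)
    trans = rng.uniform(-params.affine_translation, params.affine_translation, size=3)
    R = _euler_rotation(angles)
    mat = np.eye(4)
    mat[:3, :3] = R @ np.diag(scales)
    center = params.center
    mat[:3, 3] = trans + center - mat[:3, :3] @ center
    tag = "affine12" if max_scale > 0 else "rigid6"
    return AffineTransform(mat, tag)


def _euler_rotation(angles: np.ndarray) -> np.ndarray:
    ax, ay, az = angles
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def make_canonical_anatomy(params: PhantomParams) -> SyntheticSubject:
    """Deterministic canonical head; truth maps are the identity."""
    anat = _CanonicalAnatomy(params)
    grid = params.grid
    pts = grid.world_coords().reshape(3, -1)
    shape = grid.shape
    t1 = ScalarImage(grid, anat.t1(pts).reshape(shape))
    flair = ScalarImage(grid, anat.flair(pts).reshape(shape))
    dti = TensorImage(grid, matrices_to_components(anat.dti(pts)).reshape(shape + (6,)))
    mask = ScalarImage(grid, anat.brain_mask(pts).reshape(shape))
    return SyntheticSubject(
        id="canonical",
        age=params.reference_age,
        t1=t1,
        flair=flair,
        dti=dti,
        brain_mask=mask,
        truth_warp_to_canonical=DisplacementField.zero(grid),
        truth_affine=AffineTransform.identity(),
    )


def make_subject(params: PhantomParams, age: float, subject_seed: int,
                 subject_id: str | None = None) -> SyntheticSubject:
    """One phantom subject at the given age with a known composite truth map."""
    rng = np.random.default_rng(subject_seed)
    anat = _CanonicalAnatomy(params)
    grid = params.grid
    scale = 1.0 + params.ventricle_age_slope * (age - params.reference_age)
    if scale <= 0:
        raise ValueError("age/slope combination collapses the ventricles")

    affine = _random_affine(params, rng)
    amplitude = params.subject_warp_amplitude
    for attempt in range(4):
        rand_field = _random_smooth_field(params, amplitude, rng)
        truth = _compose_truth(grid, anat, scale, rand_field, affine)
        min_jac = jacobian_determinant_map(truth).values.min()
        if min_jac > 0:
            break
        amplitude *= 0.7
        warnings.warn(
            f"subject warp non-diffeomorphic (min |J| = {min_jac:.3g}); "
            f"regenerating with amplitude {amplitude:.2f} mm"
        )
    else:
        raise RuntimeError("could not generate a diffeomorphic subject warp")

    # subject images: canonical anatomy evaluated at phi^-1(grid points)
    inv = invert_warp(truth, tol=0.01, max_iter=50, check=False)
    src = inv.positions().reshape(3, -1)
    shape = grid.shape
    t1_vals = anat.t1(src).reshape(shape)
    flair_vals = anat.flair(src).reshape(shape)
    mask_vals = anat.brain_mask(src).reshape(shape)

    D = anat.dti(src)
    # reorient tensors with the forward anatomy map: F = J_phi at phi^-1(y),
    # equivalently the inverse Jacobian of the inverse map at y
    J_inv = jacobian_matrices(inv).reshape(-1, 3, 3)
    ok = np.abs(np.linalg.det(J_inv)) > 1e-12
    F = np.broadcast_to(np.eye(3), J_inv.shape).copy()
    F[ok] = np.linalg.inv(J_inv[ok])
    R, _ = ppd_rotation(F, D)
    D = np.einsum("...ij,...jk,...lk->...il", R, D, R)
    dti_comp = matrices_to_components(D).reshape(shape + (6,))

    sd_t1, sd_flair, sd_dti = params.noise_sd
    if sd_t1 > 0:
        t1_vals = t1_vals + rng.normal(0, sd_t1, shape)
    if sd_flair > 0:
        flair_vals = flair_vals + rng.normal(0, sd_flair, shape)
    if sd_dti > 0:
        noise = rng.normal(0, sd_dti, shape + (6,))
        dti_comp = np.where((dti_comp != 0).any(axis=-1, keepdims=True),
                            dti_comp + noise, dti_comp)

    return SyntheticSubject(
        id=subject_id if subject_id is not None else f"sub-{subject_seed}",
        age=float(age),
        t1=ScalarImage(grid, t1_vals),
        flair=ScalarImage(grid, flair_vals),
        dti=TensorImage(grid, dti_comp),
        brain_mask=ScalarImage(grid, mask_vals),
        truth_warp_to_canonical=truth,
        truth_affine=affine,
    )


def _compose_truth(grid: ImageGrid, anat: _CanonicalAnatomy, scale: float,
                   rand_field: DisplacementField,
                   affine: AffineTransform) -> DisplacementField:
    """phi(x) = A(psi_rand(psi_age(x))) evaluated on the canonical grid."""
    x = grid.world_coords()
    pts = x.reshape(3, -1)
    p1 = pts + _ventricle_expansion(pts, anat, scale)
    p1 = p1.reshape(x.shape)
    p2 = p1 + sample_displacement(rand_field, p1)
    p3 = affine.apply(p2)
    return DisplacementField(grid, np.moveaxis(p3 - x, 0, -1))


def make_cohort(params: PhantomParams, n: int, age_low: float, age_high: float,
                seed: int, ages: np.ndarray | None = None) -> SyntheticCohort:
    """Cohort with uniform (or supplied) ages and per-subject derived seeds."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if age_low >= age_high:
        raise ValueError("age_low must be < age_high")
    children = np.random.SeedSequence(seed).spawn(n + 1)
    rng = np.random.default_rng(children[0])
    if ages is None:
        ages = rng.uniform(age_low, age_high, size=n)
    else:
        ages = np.asarray(ages, dtype=float)
        if ages.shape != (n,):
            raise ValueError("ages must have length n")
        if np.any(ages < age_low) or np.any(ages >= age_high):
            raise ValueError("supplied ages outside [age_low, age_high)")
    subject_seeds = [int(s.generate_state(1)[0]) for s in children[1:]]
    subjects = [
        make_subject(params, age, sseed, subject_id=f"sub-{i:03d}")
        for i, (age, sseed) in enumerate(zip(ages, subject_seeds))
    ]
    return SyntheticCohort(subjects, params)
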