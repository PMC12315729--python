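"""Gaussian-process regression of displacement fields on age, and
age-dependent template generation.

Subjects are stratified into half-yearly age bins, each randomly split into
two sub-bins whose members are aggregated into mean displacement fields; a
GP with a squared-exponential kernel and a per-sub-bin noise weight matrix
W = diag(1/p_l) is fit to the aggregated fields (one independent output per
voxel-component, shared hyperparameters, single cached solve).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy import optimize

from .template_builder import MultimodalTemplate, _resample_and_average
from .volgeom import (
    DisplacementField,
    ImageGrid,
    compose_warps,
    invert_warp,
    jacobian_determinant_map,
)

__all__ = [
    "StratifiedTraining",
    "GPHyperparams",
    "GPModel",
    "stratify_training",
    "sq_exp_kernel",
    "gp_neg_log_marginal_likelihood",
    "fit_hyperparameters",
    "gp_predict_mean_field",
    "make_age_template",
]

#: relative diagonal jitter for factorisation stability
JITTER = 1e-8


@dataclass
class StratifiedTraining:
    """Aggregated GP training set: one row per nonempty sub-bin."""

    ages: np.ndarray          # (L,) mean age per sub-bin
    counts: np.ndarray        # (L,) p_l, subjects per sub-bin
    mean_fields: np.ndarray   # (L, V, 3) mean displacement per sub-bin
    grid: ImageGrid
    bin_width: float
    n_bins: int

    def __post_init__(self) -> None:
        L = len(self.ages)
        if self.counts.shape != (L,) or self.mean_fields.shape[0] != L:
            raise ValueError("inconsistent training shapes")
        if np.any(self.counts < 1):
            raise ValueError("sub-bin counts must be positive")

    @property
    def n_subbins(self) -> int:
        return len(self.ages)

    @property
    def weight_matrix(self) -> np.ndarray:
        """W = diag(1/p_l)."""
        return np.diag(1.0 / self.counts)


@dataclass(frozen=True)
class GPHyperparams:
    sigma_f: float   # signal scale, mm
    sigma_n: float   # noise scale, mm
    length_scale: float  # years

    def __post_init__(self) -> None:
        if min(self.sigma_f, self.sigma_n, self.length_scale) <= 0:
            raise ValueError("all hyperparameters must be strictly positive")


def stratify_training(ages, warps: list[DisplacementField], bin_width: float = 0.5,
                      subbins_per_bin: int = 2, seed: int = 0) -> StratifiedTraining:
    """Half-yearly age stratification with random sub-bin assignment.

    Each subject falls in the bin floor(age / bin_width) and is assigned to
    one of ``subbins_per_bin`` sub-bins uniformly at random (deterministic
    given ``seed``); empty sub-bins are dropped.  Warps must be the nonlinear
    deformation parts only (no affine component).
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        raise ValueError("no subjects to stratify")
    if len(warps) != ages.size:
        raise ValueError("one warp per subject required")
    grid = warps[0].grid
    for w in warps[1:]:
        if not grid.same_as(w.grid):
            raise ValueError("all warps must share one grid")
    rng = np.random.default_rng(seed)
    bin_idx = np.floor(ages / bin_width).astype(int)
    sub_idx = rng.integers(0, subbins_per_bin, size=ages.size)
    groups: dict[tuple[int, int], list[int]] = {}
    for i, (b, s) in enumerate(zip(bin_idx, sub_idx)):
        groups.setdefault((b, int(s)), []).append(i)
    keys = sorted(groups)
    x, p, y = [], [], []
    for key in keys:
        members = groups[key]
        x.append(ages[members].mean())
        p.append(len(members))
        y.append(np.mean([warps[i].disp for i in members], axis=0).reshape(-1, 3))
    return StratifiedTraining(
        ages=np.array(x), counts=np.array(p, dtype=float),
        mean_fields=np.stack(y), grid=grid, bin_width=bin_width,
        n_bins=len({b for b, _ in keys}),
    )


def sq_exp_kernel(x, x_prime, hyper: GPHyperparams) -> np.ndarray:
    """k(x, x') = sigma_f^2 exp(-(x - x')^2 / (2 l^2)), broadcasting inputs."""
    x = np.asarray(x, dtype=float)
    x_prime = np.asarray(x_prime, dtype=float)
    d = np.subtract.outer(x, x_prime)
    return hyper.sigma_f ** 2 * np.exp(-(d ** 2) / (2.0 * hyper.length_scale ** 2))


def _regularised_cov(hyper: GPHyperparams, training: StratifiedTraining) -> np.ndarray:
    K = sq_exp_kernel(training.ages, training.ages, hyper)
    A = K + hyper.sigma_n ** 2 * training.weight_matrix
    A[np.diag_indices_from(A)] += JITTER * hyper.sigma_f ** 2
    return A


def _training_columns(training: StratifiedTraining,
                      voxel_sample: np.ndarray | None,
                      components: str = "all") -> np.ndarray:
    """(L, M) output matrix restricted to sampled voxels/components."""
    Y = training.mean_fields
    if voxel_sample is not None:
        Y = Y[:, np.asarray(voxel_sample, dtype=int), :]
    if components == "all":
        return Y.reshape(Y.shape[0], -1)
    if components == "single":
        return Y[..., 0]
    raise ValueError("components must be 'all' or 'single'")


def gp_neg_log_marginal_likelihood(hyper: GPHyperparams,
                                   training: StratifiedTraining,
                                   voxel_sample: np.ndarray | None = None,
                                   components: str = "all") -> float:
    """0.5 y^T (K + sigma_n^2 W)^-1 y + 0.5 log|K + sigma_n^2 W| summed over
    the sampled voxel-components (constant terms dropped)."""
    A = _regularised_cov(hyper, training)
    try:
        cho = sla.cho_factor(A, lower=True)
    except sla.LinAlgError as exc:
        raise RuntimeError(f"factorisation failed for {hyper}") from exc
    Y = _training_columns(training, voxel_sample, components)
    quad = float(np.sum(Y * sla.cho_solve(cho, Y)))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    return 0.5 * quad + 0.5 * Y.shape[1] * logdet


def fit_hyperparameters(training: StratifiedTraining, n_voxels: int = 10000,
                        seed: int = 0, init: GPHyperparams | None = None,
                        components: str = "all",
                        max_evals: int = 2000) -> GPHyperparams:
    """Nelder-Mead minimisation of the negated marginal likelihood over
    (log sigma_f, log sigma_n, log l) on a random voxel subsample."""
    rng = np.random.default_rng(seed)
    n_total = training.mean_fields.shape[1]
    if n_voxels < n_total:
        voxel_sample = rng.choice(n_total, size=n_voxels, replace=False)
        voxel_sample.sort()
    else:
        voxel_sample = None
    if init is None:
        norms = np.linalg.norm(training.mean_fields, axis=-1)
        sigma_f0 = max(float(norms.std()), 1e-3)
        init = GPHyperparams(sigma_f0, 0.5 * sigma_f0, 10.0)
    x0 = np.log([init.sigma_f, init.sigma_n, init.length_scale])

    def objective(logp):
        hyper = GPHyperparams(*np.exp(logp))
        try:
            return gp_neg_log_marginal_likelihood(hyper, training, voxel_sample,
                                                  components)
        except RuntimeError:
            return np.inf

    res = optimize.minimize(objective, x0, method="Nelder-Mead",
                            options={"xatol": 1e-4, "fatol": 1e-8,
                                     "maxfev": max_evals, "adaptive": True})
    if not res.success:
        warnings.warn(f"hyperparameter optimisation did not converge: {res.message}")
    return GPHyperparams(*np.exp(res.x))


@dataclass
class GPModel:
    """Fitted GP with the cached solve of (K + sigma_n^2 W) Ybar."""

    hyper: GPHyperparams
    training: StratifiedTraining

    def __post_init__(self) -> None:
        A = _regularised_cov(self.hyper, self.training)
        self._cho = sla.cho_factor(A, lower=True)
        Y = self.training.mean_fields.reshape(self.training.n_subbins, -1)
        self._alpha = sla.cho_solve(self._cho, Y)  # (L, 3V)

    @property
    def age_range(self) -> tuple[float, float]:
        return float(self.training.ages.min()), float(self.training.ages.max())


def gp_predict_mean_field(age_star: float, model: GPModel) -> DisplacementField:
    """Predictive mean y* = k(x*, xbar) (K + sigma_n^2 W)^-1 Ybar."""
    k = sq_exp_kernel([age_star], model.training.ages, model.hyper)  # (1, L)
    y_star = (k @ model._alpha)[0]
    grid = model.training.grid
    return DisplacementField(grid, y_star.reshape(grid.shape + (3,)))


def make_age_template(age_star: float, model: GPModel,
                      fixed_template: MultimodalTemplate,
                      subject_warps: dict[str, DisplacementField],
                      cohort) -> MultimodalTemplate:
    """Age-dependent template: the predicted mean warp is inverted and
    composed with every construction subject's full warp before resampling
    and averaging the cohort's modalities (intensities derive only from the
    construction cohort).

    Predictions outside the training age range regress toward the zero prior
    mean and are warned against; non-diffeomorphic predicted warps produce a
    warning with the minimum Jacobian, not an error.
    """
    lo, hi = model.age_range
    if not lo <= age_star <= hi:
        warnings.warn(
            f"age {age_star} is outside the training range [{lo:.1f}, {hi:.1f}]; "
            "the prediction reverts toward the prior mean")
    psi_bar = gp_predict_mean_field(age_star, model)
    min_jac = float(jacobian_determinant_map(psi_bar).values.min())
    if min_jac <= 0:
        warnings.warn(
            f"predicted warp for age {age_star} is not diffeomorphic "
            f"(min Jacobian {min_jac:.3g}); proceeding")
    psi_inv = invert_warp(psi_bar, tol=0.01, max_iter=50, check=False)
    composed = {
        sid: compose_warps(warp, psi_inv) for sid, warp in subject_warps.items()
    }
    template = _resample_and_average(
        cohort, composed, fixed_template.grid, fixed_template.iteration,
        {"stage": "adt", "age": age_star, "min_jacobian": min_jac},
    )
    return template
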