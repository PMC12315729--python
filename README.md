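# omtemplate

Unbiased multimodal brain-template construction at desk scale: an iterative
groupwise template builder for two scalar channels ("T1-like",
"FLAIR-like") plus a diffusion-tensor channel, and a Gaussian-process model
over deformation fields that predicts age-dependent templates. Everything is
exercised end-to-end on synthetic multimodal head phantoms with known
ground-truth deformations.

## What it does

1. **Phantom cohort** (`omtemplate.phantom`) — deterministic canonical head
   (scalp/skull/GM/WM shells, mirrored ventricles, a C-shaped anisotropic
   tract) plus per-subject age-dependent ventricle expansion, smooth random
   warps, affine jitter and noise. The exact composite map from canonical
   space to each subject is retained as ground truth.
2. **Affine stage** (`omtemplate.affine_stage`) — pairwise affine
   registration to a seed subject, matrix-log ("midtrans"-style) midspace
   unbiasing, voxel-wise median template, soft masks, the 8:1
   intra/extracranial weight-mask recipe, DTI mask erosion and smooth scalp
   clamping.
3. **Nonlinear templating** (`omtemplate.mmreg`, `omtemplate.template_builder`)
   — multiresolution multimodal registration (MSE for scalars, mean squared
   Frobenius difference with finite-strain reorientation for tensors,
   bending-energy regularisation, per-channel cost rescaling) and the
   iterate–unbias–resample–average loop: the mean warp is inverted and
   composed into every subject's warp, channels are resampled in one step
   (spline for intensities, preservation-of-principal-directions for
   tensors, trilinear for masks), averaged (log-Euclidean over valid voxels
   for tensors) and intensity-normalised to a nonbackground mean of 1000.
4. **Age-dependent templates** (`omtemplate.gp_adt`) — half-yearly age
   stratification with two random sub-bins per bin, a squared-exponential
   GP with noise weight matrix `W = diag(1/p_l)`, Nelder–Mead
   hyperparameter fitting over sampled voxels, predictive mean deformation
   fields, and template generation by composing the inverted predicted warp
   with the construction warps.
5. **Evaluation** (`omtemplate.evalqc`) — RMS/RMSP/PC/FN convergence
   metrics, Jacobian-determinant ROI volumetrics, log-Jacobian maps, and
   pairwise Dice analysis with relative differences between registration
   targets.

The geometric core (`omtemplate.volgeom`) provides the image/tensor/warp
types, warp composition and fixed-point inversion, Jacobians, spline/PPD
resampling, log-Euclidean tensor averaging and NIfTI / plain-text affine
I/O.

## Conventions

- All geometry flows through the NIfTI voxel-to-world affine; voxel indices
  are 0-based, world units are mm.
- A displacement field on grid `G` represents `phi(x) = x + d(x)` in world
  mm and is a *pullback* resampling map: it is defined on the space you
  resample **into** and points at the space you sample **from**
  (template → subject).
- Tensor volumes are 4-D NIfTI with 6 components in lower-triangle row
  order: `Dxx, Dxy, Dxz, Dyy, Dyz, Dzz`. Voxels with zero or
  non-positive-definite tensors are treated as invalid (missing data).
- Affine files are plain-text whitespace-separated 4×4 world-to-world (mm)
  matrices.

## CLI

```bash
omtemplate phantom --n 10 --age-range 45 82 --seed 0 --out work/cohort
omtemplate build-affine --cohort work/cohort/manifest.csv --out work/affine
omtemplate build-template --cohort work/cohort/manifest.csv \
    --affine-dir work/affine --levels 2 --iterations 2 --out work/template
omtemplate fit-gp --warps work/template --ages work/cohort/manifest.csv \
    --out work/gp
omtemplate predict-adt --model work/gp --template work/template/template \
    --warps work/template --cohort work/cohort/manifest.csv --age 75 \
    --out work/adt
omtemplate evaluate --warps work/adt --out work/eval
omtemplate run --out work/pipeline --seed 0    # full pipeline, resumable
```

`omtemplate run` executes phantom → affine → template → GP → ADT →
evaluation with per-stage caching: re-running with an unchanged
configuration skips completed stages, and changing a stage's configuration
invalidates only that stage and its downstream stages.

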