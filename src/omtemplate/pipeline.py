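"""End-to-end pipeline: phantom cohort -> affine template -> nonlinear
template -> GP fit -> age-dependent templates -> evaluation.

Every stage is idempotent: it writes its artefacts plus a ``.stage.json``
provenance record (config hash and seed) and is skipped on re-run when the
record matches the current configuration.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evalqc
from .affine_stage import AffineSet, build_affine_template
from .gp_adt import GPModel, StratifiedTraining, fit_hyperparameters, \
    gp_predict_mean_field, make_age_template, stratify_training
from .phantom import PhantomParams, SyntheticCohort, SyntheticSubject, \
    canonical_ventricle_mask, make_canonical_anatomy, make_cohort
from .template_builder import MultimodalTemplate, TemplateLevel, \
    default_template_schedule, run_hierarchy
from .volgeom import (
    DisplacementField,
    WeightImage,
    jacobian_determinant_map,
    load_affine,
    load_displacement,
    load_scalar,
    load_tensor,
    save_affine,
    save_displacement,
    save_scalar,
    save_tensor,
)

__all__ = ["PipelineConfig", "run_pipeline", "save_cohort", "load_cohort",
           "save_template_bundle", "load_template_bundle"]


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    n_subjects: int = 10
    age_low: float = 45.0
    age_high: float = 82.0
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size: float = 3.0
    ventricle_age_slope: float = 0.004
    subject_warp_amplitude: float = 2.0
    template_levels: list[dict] = field(default_factory=lambda: [
        {"finest_spacing": 32.0, "finest_fwhm": 8.0, "iterations": 1},
        {"finest_spacing": 16.0, "finest_fwhm": 4.0, "iterations": 1},
    ])
    gp_bin_width: float = 0.5
    gp_subbins_per_bin: int = 2
    gp_n_voxels: int = 10000
    adt_ages: list[float] = field(default_factory=lambda: [50.0, 60.0, 70.0, 80.0])

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = PipelineConfig(**raw)
        cfg.grid_shape = tuple(cfg.grid_shape)
        return cfg

    def phantom_params(self) -> PhantomParams:
        return PhantomParams(
            grid_shape=self.grid_shape, voxel_size=self.voxel_size,
            ventricle_age_slope=self.ventricle_age_slope,
            subject_warp_amplitude=self.subject_warp_amplitude,
        )

    def template_schedule(self) -> list[TemplateLevel]:
        if not self.template_levels:
            return default_template_schedule()
        return [TemplateLevel(**lvl) for lvl in self.template_levels]

    def digest(self, keys: list[str] | None = None) -> str:
        data = asdict(self)
        if keys is not None:
            data = {k: data[k] for k in keys}
        return hashlib.sha256(
            json.dumps(data, sort_keys=True, default=str).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# cohort and template persistence

def save_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sub in cohort.subjects:
        base = out / sub.id
        save_scalar(sub.t1, f"{base}_t1.nii.gz")
        save_scalar(sub.flair, f"{base}_flair.nii.gz")
        save_tensor(sub.dti, f"{base}_dti.nii.gz")
        save_scalar(sub.brain_mask, f"{base}_mask.nii.gz")
        save_displacement(sub.truth_warp_to_canonical, f"{base}_truthwarp.nii.gz")
        save_affine(sub.truth_affine, f"{base}_truthaffine.txt")
        rows.append({
            "id": sub.id, "age": sub.age,
            "t1": f"{sub.id}_t1.nii.gz", "flair": f"{sub.id}_flair.nii.gz",
            "dti": f"{sub.id}_dti.nii.gz", "mask": f"{sub.id}_mask.nii.gz",
            "truth_warp": f"{sub.id}_truthwarp.nii.gz",
            "truth_affine": f"{sub.id}_truthaffine.txt",
        })
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(manifest: str | Path,
                params: PhantomParams | None = None) -> SyntheticCohort:
    manifest = Path(manifest)
    base = manifest.parent
    df = pd.read_csv(manifest)
    subjects = []
    for _, row in df.iterrows():
        subjects.append(SyntheticSubject(
            id=row["id"], age=float(row["age"]),
            t1=load_scalar(base / row["t1"]),
            flair=load_scalar(base / row["flair"]),
            dti=load_tensor(base / row["dti"]),
            brain_mask=load_scalar(base / row["mask"]),
            truth_warp_to_canonical=load_displacement(base / row["truth_warp"]),
            truth_affine=load_affine(base / row["truth_affine"]),
        ))
    return SyntheticCohort(subjects, params or PhantomParams())


def save_template_bundle(template: MultimodalTemplate, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_scalar(template.t1, out / "t1.nii.gz")
    save_scalar(template.flair, out / "flair.nii.gz")
    save_tensor(template.dti, out / "dti.nii.gz")
    save_scalar(type(template.t1)(template.grid, template.soft_t1_mask.weights),
                out / "soft_t1_mask.nii.gz")
    save_scalar(type(template.t1)(template.grid, template.soft_dti_mask.weights),
                out / "soft_dti_mask.nii.gz")
    with open(out / "provenance.json", "w") as fh:
        json.dump({"iteration": template.iteration,
                   "provenance": template.provenance}, fh, indent=2, default=str)


def load_template_bundle(bundle_dir: str | Path) -> MultimodalTemplate:
    d = Path(bundle_dir)
    with open(d / "provenance.json") as fh:
        meta = json.load(fh)
    t1 = load_scalar(d / "t1.nii.gz")
    return MultimodalTemplate(
        t1=t1,
        flair=load_scalar(d / "flair.nii.gz"),
        dti=load_tensor(d / "dti.nii.gz"),
        soft_t1_mask=WeightImage(t1.grid, np.clip(
            load_scalar(d / "soft_t1_mask.nii.gz").values, 0, None)),
        soft_dti_mask=WeightImage(t1.grid, np.clip(
            load_scalar(d / "soft_dti_mask.nii.gz").values, 0, None)),
        iteration=meta["iteration"],
        provenance=meta["provenance"],
    )


# ---------------------------------------------------------------------------
# stages

def _stage_done(stage_dir: Path, digest: str) -> bool:
    record = stage_dir / ".stage.json"
    if not record.exists():
        return False
    try:
        with open(record) as fh:
            return json.load(fh).get("digest") == digest
    except (OSError, json.JSONDecodeError):
        return False


def _mark_stage(stage_dir: Path, digest: str, seconds: float) -> None:
    with open(stage_dir / ".stage.json", "w") as fh:
        json.dump({"digest": digest, "seconds": round(seconds, 2)}, fh)


def _stage(name: str, cfg: PipelineConfig, keys: list[str], fn, log) -> Path:
    out = Path(cfg.out_dir) / name
    digest = cfg.digest(keys)
    if _stage_done(out, digest):
        log(f"[{name}] up to date, skipping")
        return out
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    fn(out)
    _mark_stage(out, digest, time.time() - t0)
    log(f"[{name}] done in {time.time() - t0:.1f}s")
    return out


_PHANTOM_KEYS = ["seed", "n_subjects", "age_low", "age_high", "grid_shape",
                 "voxel_size", "ventricle_age_slope", "subject_warp_amplitude"]
_TEMPLATE_KEYS = _PHANTOM_KEYS + ["template_levels"]
_GP_KEYS = _TEMPLATE_KEYS + ["gp_bin_width", "gp_subbins_per_bin", "gp_n_voxels"]
_ADT_KEYS = _GP_KEYS + ["adt_ages"]


def run_pipeline(cfg: PipelineConfig, log=print) -> int:
    """Execute all stages; returns 0 on success (raises on stage failure)."""
    params = cfg.phantom_params()

    def do_phantom(out: Path):
        cohort = make_cohort(params, cfg.n_subjects, cfg.age_low, cfg.age_high,
                             seed=cfg.seed)
        save_cohort(cohort, out)

    phantom_dir = _stage("phantom", cfg, _PHANTOM_KEYS, do_phantom, log)
    cohort = load_cohort(phantom_dir / "manifest.csv", params)
    canonical = make_canonical_anatomy(params)

    def do_affine(out: Path):
        template, affines = build_affine_template(cohort, reference=canonical.t1)
        save_template_bundle(template, out / "template")
        for sid, aff in affines.transforms.items():
            save_affine(aff, out / f"{sid}_affine.txt")
        with open(out / "affines.json", "w") as fh:
            json.dump({"reference_id": affines.reference_id,
                       "subjects": sorted(affines.transforms)}, fh)

    affine_dir = _stage("affine", cfg, _PHANTOM_KEYS, do_affine, log)
    affine_template = load_template_bundle(affine_dir / "template")
    with open(affine_dir / "affines.json") as fh:
        meta = json.load(fh)
    affines = AffineSet(
        {sid: load_affine(affine_dir / f"{sid}_affine.txt")
         for sid in meta["subjects"]},
        meta["reference_id"])

    def do_template(out: Path):
        template, last, report = run_hierarchy(
            cohort, affine_template, affines, schedule=cfg.template_schedule())
        save_template_bundle(template, out / "template")
        report.to_dataframe().to_csv(out / "convergence.csv", index=False)
        for sid, warp in last.composed_warps.items():
            save_displacement(warp, out / f"{sid}_warp.nii.gz")
        for sid, warp in last.nonlinear_warps.items():
            save_displacement(warp, out / f"{sid}_nonlinear.nii.gz")

    template_dir = _stage("template", cfg, _TEMPLATE_KEYS, do_template, log)
    template = load_template_bundle(template_dir / "template")
    composed = {s.id: load_displacement(template_dir / f"{s.id}_warp.nii.gz")
                for s in cohort.subjects}
    nonlinear = {s.id: load_displacement(template_dir / f"{s.id}_nonlinear.nii.gz")
                 for s in cohort.subjects}

    def do_gp(out: Path):
        training = stratify_training(
            cohort.ages, [nonlinear[s.id] for s in cohort.subjects],
            bin_width=cfg.gp_bin_width, subbins_per_bin=cfg.gp_subbins_per_bin,
            seed=cfg.seed)
        hyper = fit_hyperparameters(training, n_voxels=cfg.gp_n_voxels,
                                    seed=cfg.seed)
        with open(out / "model.json", "w") as fh:
            json.dump({
                "sigma_f": hyper.sigma_f, "sigma_n": hyper.sigma_n,
                "length_scale": hyper.length_scale,
                "ages": training.ages.tolist(),
                "counts": training.counts.tolist(),
                "bin_width": training.bin_width, "n_bins": training.n_bins,
            }, fh, indent=2)
        for l in range(training.n_subbins):
            save_displacement(
                DisplacementField(training.grid,
                                  training.mean_fields[l].reshape(
                                      training.grid.shape + (3,))),
                out / f"subbin_{l:03d}.nii.gz")

    gp_dir = _stage("gp", cfg, _GP_KEYS, do_gp, log)
    model = load_gp_model(gp_dir)

    def do_adt(out: Path):
        for age in cfg.adt_ages:
            psi = gp_predict_mean_field(age, model)
            save_displacement(psi, out / f"adt_{age:g}_warp.nii.gz")
            adt = make_age_template(age, model, template, composed, cohort)
            save_template_bundle(adt, out / f"adt_{age:g}")

    adt_dir = _stage("adt", cfg, _ADT_KEYS, do_adt, log)

    def do_evaluate(out: Path):
        vent = canonical_ventricle_mask(params)
        rows = []
        for age in cfg.adt_ages:
            warp = load_displacement(adt_dir / f"adt_{age:g}_warp.nii.gz")
            jac = jacobian_determinant_map(warp)
            logj, n_masked = evalqc.log_jacobian_map(warp)
            save_scalar(logj, out / f"adt_{age:g}_logjac.nii.gz")
            rows.append({
                "age": age,
                "ventricle_volume_mm3": evalqc.roi_volume_from_jacobian(jac, vent),
                "min_jacobian": float(jac.values.min()),
                "n_nonpositive_jacobian": n_masked,
            })
        pd.DataFrame(rows).to_csv(out / "adt_volumetrics.csv", index=False)

    _stage("evaluate", cfg, _ADT_KEYS, do_evaluate, log)
    return 0


def load_gp_model(gp_dir: str | Path) -> GPModel:
    gp_dir = Path(gp_dir)
    with open(gp_dir / "model.json") as fh:
        meta = json.load(fh)
    fields = []
    for l in range(len(meta["ages"])):
        fields.append(load_displacement(gp_dir / f"subbin_{l:03d}.nii.gz"))
    grid = fields[0].grid
    training = StratifiedTraining(
        ages=np.array(meta["ages"]), counts=np.array(meta["counts"]),
        mean_fields=np.stack([f.disp.reshape(-1, 3) for f in fields]),
        grid=grid, bin_width=meta["bin_width"], n_bins=meta["n_bins"])
    from .gp_adt import GPHyperparams

    hyper = GPHyperparams(meta["sigma_f"], meta["sigma_n"], meta["length_scale"])
    return GPModel(hyper, training)
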