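"""Validation machinery: Jacobian volumetrics, Dice analyses, log-Jacobian maps."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .volgeom import DisplacementField, GridMismatchError, ScalarImage, \
    jacobian_determinant_map

__all__ = [
    "MNI152_CEREBRAL_VOLUME_MM3",
    "OMM1_CEREBRAL_VOLUME_MM3",
    "cerebral_volume_comparison",
    "DiceTable",
    "roi_volume_from_jacobian",
    "dice",
    "pairwise_dice_analysis",
    "log_jacobian_map",
    "dice_difference_test",
]

#: published cerebral volumes of the two reference templates (mm^3)
MNI152_CEREBRAL_VOLUME_MM3 = 1_884_594.0
OMM1_CEREBRAL_VOLUME_MM3 = 1_419_081.0


def cerebral_volume_comparison() -> dict[str, float]:
    """Scale comparison of the two published reference templates.

    Returns the MNI152/OMM1 volume ratio and their difference in ml.
    """
    diff_ml = (MNI152_CEREBRAL_VOLUME_MM3 - OMM1_CEREBRAL_VOLUME_MM3) / 1000.0
    ratio = MNI152_CEREBRAL_VOLUME_MM3 / OMM1_CEREBRAL_VOLUME_MM3
    return {"ratio": ratio, "difference_ml": diff_ml}


def roi_volume_from_jacobian(jac: ScalarImage, roi_mask: ScalarImage) -> float:
    """ROI volume in mm^3: sum of Jacobian determinants over the ROI times
    the voxel volume."""
    if not jac.grid.same_as(roi_mask.grid):
        raise GridMismatchError("Jacobian map and ROI must share a grid")
    roi = roi_mask.values > 0.5
    if not np.any(roi):
        raise ValueError("ROI is empty")
    return float(jac.values[roi].sum() * jac.grid.voxel_volume)


def dice(a, b) -> float:
    """Dice coefficient 2|A n B| / (|A| + |B|); NaN when both masks are empty."""
    av = (a.values if isinstance(a, ScalarImage) else np.asarray(a)) > 0.5
    bv = (b.values if isinstance(b, ScalarImage) else np.asarray(b)) > 0.5
    if av.shape != bv.shape:
        raise GridMismatchError("masks must share a grid")
    denom = av.sum() + bv.sum()
    if denom == 0:
        return float("nan")
    return float(2.0 * np.logical_and(av, bv).sum() / denom)


@dataclass
class DiceTable:
    """Pairwise Dice matrices per (target, ROI) with aggregated means."""

    matrices: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    subjects: list[str] = field(default_factory=list)

    def mean(self, target: str, roi: str) -> float:
        m = self.matrices[(target, roi)]
        iu = np.triu_indices_from(m, k=1)
        vals = m[iu]
        return float(np.nanmean(vals))

    def means_frame(self) -> pd.DataFrame:
        rois = sorted({r for _, r in self.matrices})
        targets = sorted({t for t, _ in self.matrices})
        return pd.DataFrame(
            {t: [self.mean(t, r) for r in rois] for t in targets}, index=rois)

    def relative_difference(self, target_a: str, target_b: str) -> pd.Series:
        """(mean pairwise Dice with target_a - mean with target_b) / mean
        with target_b, per ROI."""
        rois = sorted({r for t, r in self.matrices if t == target_a})
        out = {}
        for roi in rois:
            a = self.mean(target_a, roi)
            b = self.mean(target_b, roi)
            out[roi] = (a - b) / b
        return pd.Series(out, name=f"{target_a}_vs_{target_b}")


def pairwise_dice_analysis(roi_masks: dict[str, dict[str, dict[str, ScalarImage]]],
                           threshold: float = 0.5) -> DiceTable:
    """All unordered subject-pair Dice coefficients per ROI per target.

    ``roi_masks[target][subject][roi]`` holds each subject's ROI mask warped
    into the target's space (continuous-valued masks are binarised at 0.5).
    Missing masks skip the affected pairs.
    """
    table = DiceTable()
    for target, by_subject in roi_masks.items():
        subjects = sorted(by_subject)
        if len(subjects) < 2:
            raise ValueError(f"target {target!r} needs >= 2 subjects")
        if not table.subjects:
            table.subjects = subjects
        rois = sorted({r for s in subjects for r in by_subject[s]})
        for roi in rois:
            n = len(subjects)
            m = np.full((n, n), np.nan)
            for i in range(n):
                for j in range(i + 1, n):
                    ma = by_subject[subjects[i]].get(roi)
                    mb = by_subject[subjects[j]].get(roi)
                    if ma is None or mb is None:
                        continue
                    av = (ma.values if isinstance(ma, ScalarImage)
                          else np.asarray(ma)) > threshold
                    bv = (mb.values if isinstance(mb, ScalarImage)
                          else np.asarray(mb)) > threshold
                    denom = av.sum() + bv.sum()
                    val = float("nan") if denom == 0 else \
                        float(2.0 * np.logical_and(av, bv).sum() / denom)
                    m[i, j] = m[j, i] = val
            table.matrices[(target, roi)] = m
    return table


def log_jacobian_map(warp: DisplacementField) -> tuple[ScalarImage, int]:
    """Natural log of the Jacobian determinant.

    Voxels with non-positive determinant are masked to 0 and counted in the
    returned (map, n_masked) pair.
    """
    jac = jacobian_determinant_map(warp)
    vals = jac.values
    bad = vals <= 0
    out = np.zeros_like(vals)
    out[~bad] = np.log(vals[~bad])
    return ScalarImage(jac.grid, out), int(bad.sum())


def dice_difference_test(table: DiceTable, target_a: str, target_b: str) -> dict:
    """Paired two-sided Wilcoxon signed-rank across ROIs on the per-ROI mean
    Dice of the two targets.

    Note: this is a repository choice of test, not a published procedure.
    """
    rois = sorted({r for t, r in table.matrices if t == target_a})
    a = np.array([table.mean(target_a, r) for r in rois])
    b = np.array([table.mean(target_b, r) for r in rois])
    if np.allclose(a, b):
        return {"statistic": 0.0, "pvalue": 1.0, "n_rois": len(rois)}
    res = stats.wilcoxon(a, b, alternative="two-sided")
    return {"statistic": float(res.statistic), "pvalue": float(res.pvalue),
            "n_rois": len(rois)}
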