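"""Lesion segmentation evaluation: voxel-wise, lesion-wise and cohort metrics.

Voxel-wise: Dice similarity coefficient DSC = 2|P∩R| / (|P|+|R|), precision
PPV = |P∩R| / |P| and sensitivity TPR = |P∩R| / |R|.  Lesion-wise metrics
operate on connected components (26-connectivity by default): LTPR is the
fraction of reference lesions touched by at least one predicted voxel, LFPR
the fraction of predicted lesions touching no reference voxel.  VC is the
Pearson correlation of total lesion volumes across a cohort.  The composite

    Score = DSC/8 + PPV/8 + LTPR/4 + (1 - LFPR)/4 + VC/4

weights lesion-wise detection most heavily; a perfect segmentation scores 1.
Scores here are raw values on [0, 1]; multiply by 100 for the conventional
percentage display.

Empty-mask conventions (documented, testable): empty prediction and empty
reference count as perfect agreement (DSC = PPV = TPR = LTPR = 1, LFPR = 0);
an empty prediction against a nonempty reference scores zero everywhere
except LFPR = 0 (no predicted lesion can be false).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.stats import pearsonr

from .fusion import CONNECTIVITY_26

__all__ = [
    "MetricReport",
    "voxel_metrics",
    "lesion_metrics",
    "volume_correlation",
    "score",
    "evaluate_against_raters",
    "connectivity_structure",
]

#: Score weights on (DSC, PPV, LTPR, 1-LFPR, VC)
SCORE_WEIGHTS = (0.125, 0.125, 0.25, 0.25, 0.25)


def connectivity_structure(connectivity: int = 26) -> np.ndarray:
    """3D structuring element for lesion counting (26 default, 18 or 6)."""
    if connectivity == 26:
        return CONNECTIVITY_26
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError(f"unsupported connectivity {connectivity}")


@dataclass
class MetricReport:
    dsc: float
    ppv: float
    tpr: float
    ltpr: float
    lfpr: float
    vc: Optional[float] = None

    @property
    def score(self) -> float:
        if self.vc is None:
            raise ValueError("score requires the cohort volume correlation (vc)")
        return score(self)

    def as_dict(self) -> dict:
        d = {
            "dsc": self.dsc,
            "ppv": self.ppv,
            "tpr": self.tpr,
            "ltpr": self.ltpr,
            "lfpr": self.lfpr,
        }
        if self.vc is not None:
            d["vc"] = self.vc
            d["score"] = self.score
        return d


def _check_pair(pred, ref) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred).astype(bool)
    ref = np.asarray(ref).astype(bool)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    return pred, ref


def voxel_metrics(pred, ref) -> tuple[float, float, float]:
    """(DSC, PPV, TPR) of a prediction-reference mask pair."""
    pred, ref = _check_pair(pred, ref)
    tp = int((pred & ref).sum())
    p, r = int(pred.sum()), int(ref.sum())
    if p == 0 and r == 0:
        return 1.0, 1.0, 1.0
    dsc = 2 * tp / (p + r)
    ppv = tp / p if p else 0.0
    tpr = tp / r if r else 0.0
    return dsc, ppv, tpr


def lesion_metrics(pred, ref, connectivity: int = 26) -> tuple[float, float]:
    """(LTPR, LFPR) by connected-component overlap (>= 1 shared voxel)."""
    pred, ref = _check_pair(pred, ref)
    struct = connectivity_structure(connectivity)
    ref_lab, n_ref = ndimage.label(ref, structure=struct)
    pred_lab, n_pred = ndimage.label(pred, structure=struct)
    if n_ref == 0:
        ltpr = 1.0 if n_pred == 0 else 0.0
    else:
        detected = np.unique(ref_lab[pred & ref])
        ltpr = len(detected[detected > 0]) / n_ref
    if n_pred == 0:
        lfpr = 0.0
    else:
        true_pred = np.unique(pred_lab[pred & ref])
        lfpr = (n_pred - len(true_pred[true_pred > 0])) / n_pred
    return ltpr, lfpr


def volume_correlation(cohort: Sequence[tuple[np.ndarray, np.ndarray]]) -> float:
    """Pearson r between predicted and reference total lesion volumes."""
    if len(cohort) < 2:
        raise ValueError("volume correlation needs at least two subjects")
    pv = np.array([float(np.asarray(p).astype(bool).sum()) for p, _ in cohort])
    rv = np.array([float(np.asarray(r).astype(bool).sum()) for _, r in cohort])
    if pv.std() == 0 or rv.std() == 0:
        raise ValueError("volume correlation undefined for zero-variance volumes")
    return float(pearsonr(pv, rv).statistic)


def score(report: MetricReport) -> float:
    """Weighted composite of the five components (weights 1/8,1/8,1/4,1/4,1/4)."""
    if report.vc is None:
        raise ValueError("score requires vc")
    w = SCORE_WEIGHTS
    return (
        w[0] * report.dsc
        + w[1] * report.ppv
        + w[2] * report.ltpr
        + w[3] * (1.0 - report.lfpr)
        + w[4] * report.vc
    )


def evaluate_pair(pred, ref, vc: Optional[float] = None, connectivity: int = 26) -> MetricReport:
    """All per-pair metrics for one prediction against one reference."""
    dsc, ppv, tpr = voxel_metrics(pred, ref)
    ltpr, lfpr = lesion_metrics(pred, ref, connectivity=connectivity)
    return MetricReport(dsc, ppv, tpr, ltpr, lfpr, vc)


def evaluate_against_raters(
    pred,
    rater_masks: Sequence[np.ndarray],
    vc_per_rater: Optional[Sequence[float]] = None,
    connectivity: int = 26,
) -> MetricReport:
    """Average the per-rater metric reports (challenge protocol for 2 raters)."""
    if len(rater_masks) == 0:
        raise ValueError("need at least one reference")
    if vc_per_rater is not None and len(vc_per_rater) != len(rater_masks):
        raise ValueError("one vc per rater, or none")
    reports = [
        evaluate_pair(pred, r, None if vc_per_rater is None else vc_per_rater[i], connectivity)
        for i, r in enumerate(rater_masks)
    ]
    mean = lambda attr: float(np.mean([getattr(rep, attr) for rep in reports]))
    vc = mean("vc") if vc_per_rater is not None else None
    return MetricReport(mean("dsc"), mean("ppv"), mean("tpr"), mean("ltpr"), mean("lfpr"), vc)
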