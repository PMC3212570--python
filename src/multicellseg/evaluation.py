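"""Segmentation quality metrics: pixel accuracy, ROC analysis, paired tests.

Conventions follow the wound-assay setting: *background* (cell-free) is the
positive class.  The false-positive rate is the fraction of cellular pixels
incorrectly tagged background; the true-positive rate is the fraction of
background pixels tagged correctly.  Patch-grid confidences must be expanded
to pixel resolution (nearest-neighbor within each patch window) before
pixel-level ROC analysis; :func:`pixel_confidence` does this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .image import InputError
from .patches import PatchGrid, labels_to_pixels


class EvaluationError(ValueError):
    """Raised when a metric is undefined for the given inputs."""


def pixel_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of pixels whose predicted label matches the truth."""
    pred = np.asarray(pred, bool)
    truth = np.asarray(truth, bool)
    if pred.shape != truth.shape:
        raise InputError("prediction and truth shapes differ")
    return float(np.mean(pred == truth))


def pixel_confidence(confidence: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """Expand a patch-grid confidence map to pixel resolution."""
    return labels_to_pixels(np.asarray(confidence, float), grid)


@dataclass(frozen=True)
class ROCCurve:
    """ROC curve over all distinct thresholds, (0,0) -> (1,1), with its AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_curve(confidence: np.ndarray, truth: np.ndarray) -> ROCCurve:
    """Pixel-level ROC of a confidence map against a truth mask.

    Sweeps every distinct confidence value as a threshold (ties share one
    curve point); AUC by the trapezoid rule.
    """
    scores = np.asarray(confidence, float).ravel()
    y = np.asarray(truth, bool).ravel()
    if scores.shape != y.shape:
        raise InputError("confidence and truth shapes differ")
    if y.all() or not y.any():
        raise EvaluationError("truth mask contains a single class")
    fpr, tpr, thr = _sk_roc_curve(y, scores, drop_intermediate=False)
    return ROCCurve(fpr, tpr, thr, float(np.trapezoid(tpr, fpr)))


def average_rocs(curves: list[ROCCurve],
                 fpr_grid: np.ndarray | None = None) -> ROCCurve:
    """Vertical averaging: TPR interpolated on a common FPR grid and averaged
    pointwise."""
    if not curves:
        raise EvaluationError("need at least one curve")
    grid = np.linspace(0, 1, 101) if fpr_grid is None else np.asarray(fpr_grid)
    tprs = np.vstack([np.interp(grid, c.fpr, c.tpr) for c in curves])
    mean_tpr = tprs.mean(axis=0)
    return ROCCurve(grid, mean_tpr, np.full_like(grid, np.nan),
                    float(np.trapezoid(mean_tpr, grid)))


@dataclass(frozen=True)
class MatchedAccuracy:
    accuracy: float
    threshold: float
    achieved_tpr: float
    unreachable: bool  # requested TPR exceeded every achievable TPR


def matched_threshold_accuracy(reference_tpr: float, confidence: np.ndarray,
                               truth: np.ndarray) -> MatchedAccuracy:
    """Pixel accuracy at the threshold whose TPR is the smallest value >=
    ``reference_tpr`` — the like-for-like protocol for comparing two
    confidence-producing methods at a common operating point."""
    if not 0.0 <= reference_tpr <= 1.0:
        raise InputError("reference_tpr must lie in [0, 1]")
    curve = roc_curve(confidence, truth)
    idx = np.flatnonzero(curve.tpr >= reference_tpr - 1e-12)
    unreachable = idx.size == 0
    i = int(idx[0]) if not unreachable else len(curve.tpr) - 1
    thr = curve.thresholds[i]
    scores = np.asarray(confidence, float)
    y = np.asarray(truth, bool)
    pred = scores >= thr
    return MatchedAccuracy(pixel_accuracy(pred, y), float(thr),
                           float(curve.tpr[i]), unreachable)


@dataclass(frozen=True)
class TestResult:
    p_value: float
    statistic: float
    degenerate: bool = False


def paired_accuracy_test(acc_a: list[float], acc_b: list[float]) -> TestResult:
    """Two-sided paired t-test on matched accuracy sequences."""
    a = np.asarray(acc_a, float)
    b = np.asarray(acc_b, float)
    if a.shape != b.shape or a.size < 2:
        raise InputError("paired lists must have equal length >= 2")
    diffs = a - b
    if np.allclose(diffs.std(ddof=1), 0.0):
        return TestResult(1.0, 0.0, degenerate=True)
    res = stats.ttest_rel(a, b)
    return TestResult(float(res.pvalue), float(res.statistic))


def rank_sum_test(x: list[float], y: list[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration of the U distribution for combined n <= 12 without
    ties; tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < combined.size
    method = "exact" if (combined.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(float(min(res.pvalue, 1.0)), float(res.statistic))


def evaluate_dataset(model, pairs) -> pd.DataFrame:
    """Per-image report for a trained pipeline on truth pairs:
    accuracy of the patch stage, the region-filtered stage and the final
    mask, plus the pixel-level AUC of the confidence map."""
    from .patches import build_patch_grid

    rows = []
    for i, pair in enumerate(pairs):
        res = model.segment(pair.image)
        grid = build_patch_grid(pair.image, model.patch_size)
        conf_px = pixel_confidence(res.confidence, grid)
        try:
            auc = roc_curve(conf_px, pair.mask).auc
        except EvaluationError:
            auc = np.nan
        rows.append({
            "image": i,
            "accuracy_patch": pixel_accuracy(res.patch_mask, pair.mask),
            "accuracy_region": pixel_accuracy(res.region_mask, pair.mask),
            "accuracy_final": pixel_accuracy(res.final_mask, pair.mask),
            "auc": auc,
        })
    return pd.DataFrame(rows)
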