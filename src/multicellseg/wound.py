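"""Wound-healing kinetics from per-frame segmentations.

The wound (background) area of each frame is counted, normalized to the
first frame, and fit by ordinary least squares against time.  A linear fit
is the expected kinetics for collective migration into a scratch, and the
Pearson correlation of the fit quantifies that linearity.  Treatment arms
are compared by the fold-change of median healing slopes with a Wilcoxon
rank-sum test on the per-well slopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .image import InputError
from .evaluation import rank_sum_test


@dataclass(frozen=True)
class WoundSeries:
    """Time-indexed wound areas of one well.

    Areas are background pixel counts (or um^2 when built with
    ``in_um2=True``); ``normalized_areas[0]`` is exactly 1.
    """

    times: np.ndarray
    areas: np.ndarray
    normalized_areas: np.ndarray
    pixel_size_um: float
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.times, "area": self.areas,
                             "normalized_area": self.normalized_areas})


def wound_area_series(masks: list[np.ndarray], times: list[float],
                      pixel_size_um: float = 1.0, in_um2: bool = False,
                      metadata: dict | None = None) -> WoundSeries:
    """Measure the wound-area trajectory from per-frame masks.

    The series is truncated at the first frame with zero background area:
    once opposing fronts touch, later frames no longer measure the same
    wound.  A first frame without any background cannot be normalized and is
    an error.
    """
    if len(masks) < 2:
        raise InputError("need at least 2 frames")
    times = np.asarray(times, float)
    if times.shape != (len(masks),) or np.any(np.diff(times) <= 0):
        raise InputError("times must be strictly increasing, one per frame")
    shapes = {np.asarray(m).shape for m in masks}
    if len(shapes) != 1:
        raise InputError("masks must share shape")
    counts = np.array([int(np.asarray(m, bool).sum()) for m in masks], float)
    if counts[0] == 0:
        raise InputError("first frame has zero background; cannot normalize")
    zero = np.flatnonzero(counts == 0)
    end = int(zero[0]) + 1 if zero.size else len(counts)
    counts, times = counts[:end], times[:end]
    areas = counts * pixel_size_um ** 2 if in_um2 else counts
    return WoundSeries(times, areas, areas / areas[0], pixel_size_um,
                       metadata or {})


@dataclass(frozen=True)
class HealingFit:
    """OLS fit of normalized wound area against time."""

    slope: float        # normalized area per unit time (negative = closing)
    intercept: float
    pearson_r: float
    p_value: float      # two-sided, t distribution with n-2 df; nan if n < 3
    n_points: int
    degenerate: bool = False  # constant areas: r is undefined, reported as 0

    def __post_init__(self) -> None:
        if not (np.isnan(self.pearson_r) or abs(self.pearson_r) <= 1 + 1e-12):
            raise InputError("|pearson_r| must be <= 1")


def fit_healing(series: WoundSeries) -> HealingFit:
    """Least-squares healing line; slope, Pearson r and its p-value."""
    t = series.times
    a = series.normalized_areas
    n = len(t)
    if n < 2:
        raise InputError("need at least 2 points")
    if np.allclose(a.std(), 0.0):
        return HealingFit(0.0, float(a[0]), 0.0, np.nan, n, degenerate=True)
    res = stats.linregress(t, a)
    p = float(res.pvalue) if n >= 3 else np.nan
    return HealingFit(float(res.slope), float(res.intercept),
                      float(res.rvalue), p, n)


@dataclass(frozen=True)
class TreatmentComparison:
    fold_change: float        # median |slope| treated / median |slope| untreated
    fold_change_mean: float   # same with means, reported alongside
    p_value: float            # Wilcoxon rank-sum on the slope samples


def compare_treatments(fits_treated: list[HealingFit],
                       fits_untreated: list[HealingFit]) -> TreatmentComparison:
    """Healing acceleration of a treatment: fold-change of median absolute
    slopes with a rank-sum p-value (median is robust to a failed well)."""
    if not fits_treated or not fits_untreated:
        raise InputError("need at least one fit per arm")
    st = np.abs([f.slope for f in fits_treated])
    su = np.abs([f.slope for f in fits_untreated])
    med_u = float(np.median(su))
    if med_u == 0:
        raise InputError("untreated median slope is zero; fold-change undefined")
    p = rank_sum_test(st, su).p_value
    return TreatmentComparison(float(np.median(st)) / med_u,
                               float(np.mean(st)) / float(np.mean(su)),
                               p)


def fits_table(fits: list[HealingFit], labels: list | None = None) -> pd.DataFrame:
    rows = []
    for i, f in enumerate(fits):
        rows.append({"well": labels[i] if labels else i, "slope": f.slope,
                     "intercept": f.intercept, "pearson_r": f.pearson_r,
                     "p_value": f.p_value, "n_points": f.n_points,
                     "degenerate": f.degenerate})
    return pd.DataFrame(rows)
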