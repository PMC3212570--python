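"""End-to-end segmentation pipeline: cascade -> region filter -> graph-cut.

:class:`MultiCellSeg` bundles the three stages behind a single fit/predict
estimator.  ``fit`` trains the patch cascade and then the region classifier
on (image, truth-mask) pairs; ``segment`` returns every intermediate stage
of a new image; ``predict`` returns just the final pixel mask
(True = background).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .cascade import CascadePatchClassifier, threshold_confidence
from .graphcut import refine_segmentation
from .image import CalibratedImage
from .patches import FeatureConfig, build_patch_grid, labels_to_pixels
from .regions import (RegionClassifier, compute_region_features,
                      extract_background_components, filter_regions)


@dataclass
class SegmentationResult:
    """All stages of one image's segmentation (masks: True = background)."""

    confidence: np.ndarray          # patch-grid confidence map
    patch_mask: np.ndarray          # stage "patch": thresholded cascade output
    region_mask: np.ndarray         # stage "region-filtered"
    final_mask: np.ndarray          # stage "final": graph-cut refinement
    patch_labels: np.ndarray        # patch-grid labels before region filter
    region_labels: np.ndarray       # patch-grid labels after region filter


class MultiCellSeg(BaseEstimator):
    """Classification-based segmentation of multi-cellular vs background
    regions in bright-field images.

    All parameters have fixed defaults; no per-image tuning is required.

    Parameters
    ----------
    patch_size : int, default 20
    C : float, default 1.0
        SVM regularization (cascade and region classifier).
    threshold_method : {"otsu", "svm-zero"}
    connectivity : {4, 8}
        Patch-grid connectivity for region components.
    lam : float, default 1.0
        Graph-cut pairwise strength.
    logistic_scale : float, default 1.0
        Scale of the logistic mapping confidence -> p(background).
    seed_erosion_px : int or None
        Erosion radius (px) defining hard-seed interiors; None = patch_size.
    eight_connected : bool, default False
        Use the 8-neighbor pixel graph in the refinement.
    random_state : int, default 0
    """

    def __init__(self, patch_size: int = 20, C: float = 1.0,
                 feature_config: FeatureConfig = FeatureConfig(),
                 threshold_method: str = "otsu", connectivity: int = 4,
                 lam: float = 1.0, logistic_scale: float = 1.0,
                 seed_erosion_px: int | None = None,
                 eight_connected: bool = False, random_state: int = 0):
        self.patch_size = patch_size
        self.C = C
        self.feature_config = feature_config
        self.threshold_method = threshold_method
        self.connectivity = connectivity
        self.lam = lam
        self.logistic_scale = logistic_scale
        self.seed_erosion_px = seed_erosion_px
        self.eight_connected = eight_connected
        self.random_state = random_state

    def fit(self, images: list[CalibratedImage], masks: list[np.ndarray]):
        self.cascade_ = CascadePatchClassifier(
            patch_size=self.patch_size, C=self.C,
            feature_config=self.feature_config,
            threshold_method=self.threshold_method,
            random_state=self.random_state).fit(images, masks)
        self.region_ = RegionClassifier(
            cascade=self.cascade_, C=self.C, connectivity=self.connectivity,
            random_state=self.random_state).fit(images, masks)
        return self

    def segment(self, image: CalibratedImage) -> SegmentationResult:
        grid = build_patch_grid(image, self.patch_size)
        conf = self.cascade_.decision_function(image)
        patch_labels = threshold_confidence(conf, self.threshold_method)
        comps = extract_background_components(patch_labels, self.connectivity)
        feats = [compute_region_features(image, conf, c, grid, patch_labels)
                 for c in comps]
        region_labels = filter_regions(self.region_, comps, patch_labels, feats)
        final = refine_segmentation(
            image, conf, region_labels, grid, lam=self.lam,
            logistic_scale=self.logistic_scale,
            seed_erosion_px=self.seed_erosion_px,
            eight_connected=self.eight_connected)
        return SegmentationResult(
            confidence=conf,
            patch_mask=labels_to_pixels(patch_labels, grid),
            region_mask=labels_to_pixels(region_labels, grid),
            final_mask=final,
            patch_labels=patch_labels,
            region_labels=region_labels)

    def predict(self, image: CalibratedImage) -> np.ndarray:
        return self.segment(image).final_mask

    def decision_function(self, image: CalibratedImage) -> np.ndarray:
        return self.cascade_.decision_function(image)

    # -------------------------------------------------------- serialization

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"cascade": self.cascade_.to_dict(),
             "region": self.region_.to_dict()}, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "MultiCellSeg":
        d = json.loads(Path(path).read_text())
        cascade = CascadePatchClassifier.from_dict(d["cascade"])
        obj = cls(patch_size=cascade.patch_size, C=cascade.C,
                  feature_config=cascade.feature_config,
                  threshold_method=cascade.threshold_method,
                  random_state=cascade.random_state)
        obj.cascade_ = cascade
        obj.region_ = RegionClassifier.from_dict(d["region"], cascade)
        return obj


def contour_overlay(image: CalibratedImage, mask: np.ndarray,
                    filtered_mask: np.ndarray | None = None) -> np.ndarray:
    """8-bit visualization: background contours in white, optionally the
    contours of filtered-away regions in black."""
    from skimage.segmentation import find_boundaries

    canvas = np.round(image.intensities * 255).astype(np.uint8)
    canvas[find_boundaries(np.asarray(mask, bool), mode="outer")] = 255
    if filtered_mask is not None:
        dropped = np.asarray(filtered_mask, bool) & ~np.asarray(mask, bool)
        canvas[find_boundaries(dropped, mode="outer")] = 0
    return canvas
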