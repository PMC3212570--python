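"""Region-level reclassification of background-labeled patch components.

The patch classifier occasionally mislabels clusters of textured patches as
background.  Those mistakes arrive as connected components on the patch
grid, and a whole component carries far more texture evidence than any
single patch.  A second linear SVM — the region classifier — therefore
scores each connected component of background-labeled patches and vetoes
those that look cellular.  Filtering is monotone: it can only remove
background, never create it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import convex_hull_image

from .cascade import (CascadePatchClassifier, LinearModel, Standardizer,
                      TrainingError, ModelCompatibilityError, threshold_confidence,
                      FORMAT_VERSION, _fit_linear_svm)
from .image import CalibratedImage, InputError
from .patches import PatchGrid, build_patch_grid, extract_feature_sets, pad_to_grid

#: region feature vector length: log-area, 3 confidence statistics,
#: 16-bin pooled gradient histogram, 4 pooled multi-scale SDs, solidity
N_REGION_FEATURES = 25


@dataclass
class RegionComponent:
    """A maximal connected set of background-labeled patches."""

    patch_coords: np.ndarray  # (k, 2) array of (row, col) grid indices

    def __post_init__(self) -> None:
        self.patch_coords = np.asarray(self.patch_coords, int).reshape(-1, 2)
        if len(self.patch_coords) < 1:
            raise InputError("component must contain at least one patch")

    @property
    def area(self) -> int:
        return len(self.patch_coords)

    def patch_mask(self, grid_shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(grid_shape, bool)
        m[self.patch_coords[:, 0], self.patch_coords[:, 1]] = True
        return m

    def pixel_mask(self, grid: PatchGrid) -> np.ndarray:
        m = np.zeros(grid.padded_shape, bool)
        for r, c in self.patch_coords:
            m[grid.window(r, c)] = True
        return m


def extract_background_components(patch_labels: np.ndarray,
                                  connectivity: int = 4) -> list[RegionComponent]:
    """Connected components of background-labeled patches, ordered by
    (min row, min col)."""
    labels = np.asarray(patch_labels, bool)
    if connectivity == 4:
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    elif connectivity == 8:
        structure = np.ones((3, 3), int)
    else:
        raise InputError("connectivity must be 4 or 8")
    lab, n = ndimage.label(labels, structure=structure)
    comps = []
    for i in range(1, n + 1):
        coords = np.argwhere(lab == i)
        comps.append(RegionComponent(coords))
    comps.sort(key=lambda c: (int(c.patch_coords[:, 0].min()),
                              int(c.patch_coords[:, 1].min())))
    return comps


def compute_region_features(image: CalibratedImage, confidence: np.ndarray,
                            component: RegionComponent, grid: PatchGrid,
                            patch_labels: np.ndarray | None = None) -> np.ndarray:
    """Region feature vector pooling size, confidence and texture evidence.

    Components of a genuine wound are large, high-confidence and texture-poor;
    planted or misfired components inside the monolayer keep the monolayer's
    gradient energy and multi-scale variation, which is what the pooled
    histogram and SD entries expose.
    """
    from scipy.ndimage import gaussian_filter

    conf = np.asarray(confidence, float)
    coords = component.patch_coords
    member_scores = conf[coords[:, 0], coords[:, 1]]
    if patch_labels is None:
        patch_labels = conf > 0
    bg_scores = conf[np.asarray(patch_labels, bool)]
    median_bg = float(np.median(bg_scores)) if bg_scores.size else 0.0

    padded = pad_to_grid(image.intensities, grid)
    support = component.pixel_mask(grid)
    gy, gx = np.gradient(padded)
    mag = np.hypot(gx, gy)[support]
    from .patches import MAX_GRADIENT
    hist, _ = np.histogram(mag, bins=16, range=(0.0, MAX_GRADIENT))
    total = hist.sum()
    hist = hist / total if total > 0 else np.full(16, 1 / 16)

    sds = []
    for sigma in (0.0, 1.0, 2.0, 4.0):
        sm = padded if sigma == 0 else gaussian_filter(padded, sigma, mode="reflect")
        vals = sm[support]
        sds.append(vals.std(ddof=1) if vals.size > 1 else 0.0)

    pm = component.patch_mask(conf.shape)
    hull_area = int(convex_hull_image(pm).sum()) if component.area > 1 else 1
    solidity = component.area / max(hull_area, 1)

    return np.concatenate([
        [np.log(component.area),
         float(member_scores.mean()),
         float(member_scores.min()),
         float(np.mean(member_scores > median_bg))],
        hist, sds, [solidity]])


class RegionClassifier:
    """Linear SVM over region features; vetoes false background components.

    Parameters
    ----------
    cascade : CascadePatchClassifier
        The trained patch cascade whose outputs define the components.
    C : float
        SVM regularization.
    connectivity : {4, 8}
        Patch-grid connectivity used to form components (4 by default: 8
        would merge diagonal speckle into genuine wound regions).
    truth_majority : float, default 0.5
        A training component is labeled true-background iff more than this
        fraction of its pixel support is background in the truth mask.
    random_state : int
        Seed for hard-negative synthesis.

    Attributes
    ----------
    scaler_ : Standardizer over region features
    model_ : LinearModel; positive signed distance = genuine background
    """

    def __init__(self, cascade: CascadePatchClassifier | None = None,
                 C: float = 1.0, connectivity: int = 4,
                 truth_majority: float = 0.5, random_state: int = 0):
        self.cascade = cascade
        self.C = C
        self.connectivity = connectivity
        self.truth_majority = truth_majority
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {"cascade": self.cascade, "C": self.C,
                "connectivity": self.connectivity,
                "truth_majority": self.truth_majority,
                "random_state": self.random_state}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    # ------------------------------------------------------------------ fit

    def _mine_components(self, image: CalibratedImage, mask: np.ndarray):
        """Run the cascade on a training image and label its components."""
        grid = build_patch_grid(image, self.cascade.patch_size)
        conf = self.cascade.decision_function(image)
        labels = threshold_confidence(conf, self.cascade.threshold_method)
        truth = pad_to_grid(np.asarray(mask, bool), grid)
        rows = []
        for comp in extract_background_components(labels, self.connectivity):
            feats = compute_region_features(image, conf, comp, grid, labels)
            support = comp.pixel_mask(grid)
            is_bg = truth[support].mean() > self.truth_majority
            rows.append((feats, is_bg))
        return grid, conf, labels, truth, rows

    def _synthesize_exemplars(self, image: CalibratedImage, conf: np.ndarray,
                              grid: PatchGrid, allowed: np.ndarray,
                              rng: np.random.Generator, n: int) -> list[np.ndarray]:
        """Plant component exemplars inside a patch-label mask.

        Natural training components are scarce (a well-segmented fixture
        yields roughly one genuine wound component and no misclassified
        ones), far too few to define a stable decision boundary.  Planted
        blocks of varied size and aspect ratio — drawn inside truly-cellular
        patches as hard negatives, and inside truth-background patches as
        positives of all sizes — stand in for them (seeded).
        """
        candidates = np.argwhere(allowed)
        feats = []
        for _ in range(n):
            if len(candidates) == 0:
                break
            r, c = candidates[rng.integers(len(candidates))]
            hh = int(rng.integers(1, 5))
            ww = int(rng.integers(1, 5))
            coords = [(rr, cc) for rr in range(r, min(r + hh, grid.n_rows))
                      for cc in range(c, min(c + ww, grid.n_cols))
                      if allowed[rr, cc]]
            comp = RegionComponent(np.array(coords or [[r, c]]))
            feats.append(compute_region_features(image, conf, comp, grid))
        return feats

    def fit(self, images: list[CalibratedImage], masks: list[np.ndarray]):
        if self.cascade is None or not hasattr(self.cascade, "combiner_"):
            raise TrainingError("a trained cascade is required")
        rng = np.random.default_rng(self.random_state)
        X, y = [], []
        mined = [self._mine_components(im, mk) for im, mk in zip(images, masks)]
        for _, _, _, _, rows in mined:
            for feats, is_bg in rows:
                X.append(feats)
                y.append(is_bg)
        # augment both classes with planted exemplars; see
        # _synthesize_exemplars for why natural components do not suffice
        from .patches import patch_labels_from_mask
        for (grid, conf, _, truth, _), image in zip(mined, images):
            truth_bg = patch_labels_from_mask(truth, grid, self.truth_majority)
            for feats in self._synthesize_exemplars(image, conf, grid,
                                                    ~truth_bg, rng, 8):
                X.append(feats)
                y.append(False)
            for feats in self._synthesize_exemplars(image, conf, grid,
                                                    truth_bg, rng, 8):
                X.append(feats)
                y.append(True)
        y = np.asarray(y, bool)
        if len(np.unique(y)) < 2:
            raise TrainingError(
                "region training needs both genuine and false background "
                "components; none could be mined or synthesized")
        X = np.vstack(X)
        self.scaler_ = Standardizer.fit(X)
        # balanced weighting: false-background components are rare (often
        # only the synthesized ones), and missing them is the costly error
        self.model_ = _fit_linear_svm(self.scaler_.transform(X), y, self.C,
                                      class_weight="balanced")
        return self

    # -------------------------------------------------------------- predict

    def decision_function(self, features: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(features, float))
        if X.shape[1] != len(self.scaler_.mean):
            raise ModelCompatibilityError("region feature length mismatch")
        return self.model_.signed_distance(self.scaler_.transform(X))

    def predict(self, features: np.ndarray) -> np.ndarray:
        """True = component is genuine background (kept)."""
        return self.decision_function(features) > 0

    # -------------------------------------------------------- serialization

    def to_dict(self) -> dict:
        return {"format_version": FORMAT_VERSION, "kind": "region",
                "C": self.C, "connectivity": self.connectivity,
                "truth_majority": self.truth_majority,
                "random_state": self.random_state,
                "scaler": {"mean": self.scaler_.mean.tolist(),
                           "scale": self.scaler_.scale.tolist()},
                "model": {"weights": self.model_.weights.tolist(),
                          "bias": self.model_.bias}}

    @classmethod
    def from_dict(cls, d: dict, cascade: CascadePatchClassifier | None = None):
        if d.get("kind") != "region":
            raise ModelCompatibilityError("not a region model file")
        if d.get("format_version") != FORMAT_VERSION:
            raise ModelCompatibilityError("unsupported model format version")
        obj = cls(cascade=cascade, C=d["C"], connectivity=d["connectivity"],
                  truth_majority=d["truth_majority"], random_state=d["random_state"])
        obj.scaler_ = Standardizer(np.array(d["scaler"]["mean"]),
                                   np.array(d["scaler"]["scale"]))
        obj.model_ = LinearModel(np.array(d["model"]["weights"]), d["model"]["bias"])
        return obj

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path, cascade: CascadePatchClassifier | None = None):
        return cls.from_dict(json.loads(Path(path).read_text()), cascade)


def filter_regions(model: RegionClassifier, components: list[RegionComponent],
                   patch_labels: np.ndarray,
                   features: list[np.ndarray]) -> np.ndarray:
    """Relabel components classified cellular; monotone (never adds
    background)."""
    refined = np.asarray(patch_labels, bool).copy()
    if not components:
        return refined
    keep = model.predict(np.vstack(features))
    for comp, k in zip(components, keep):
        if not k:
            refined[comp.patch_coords[:, 0], comp.patch_coords[:, 1]] = False
    return refined


def train_region_classifier(training_pairs, cascade: CascadePatchClassifier,
                            seed: int = 0, **kwargs) -> RegionClassifier:
    """Train the region classifier from (image, truth-mask) pairs."""
    model = RegionClassifier(cascade=cascade, random_state=seed, **kwargs)
    return model.fit([p.image for p in training_pairs],
                     [p.mask for p in training_pairs])


def component_table(components: list[RegionComponent], features, decisions,
                    scores) -> pd.DataFrame:
    """Flat component table (id, area, bbox, decision, score) for export."""
    rows = []
    for i, comp in enumerate(components):
        r0, c0 = comp.patch_coords.min(axis=0)
        r1, c1 = comp.patch_coords.max(axis=0)
        rows.append({"id": i, "area": comp.area, "min_row": int(r0),
                     "min_col": int(c0), "max_row": int(r1), "max_col": int(c1),
                     "kept": bool(decisions[i]), "score": float(scores[i])})
    return pd.DataFrame(rows)
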