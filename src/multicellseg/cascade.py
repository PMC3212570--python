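"""Two-stage linear-SVM cascade for patch classification.

Stage one trains one linear SVM per feature set (five in the standard
configuration); stage two ("the combiner") is a linear SVM over the 5-vector
of stage-one signed distances.  The combiner is trained on *out-of-fold*
stage-one scores via 2-fold cross-fitting: naive in-sample stacking would
feed the combiner optimistically separated scores and overfit.

Scores are signed Euclidean distances to the separating hyperplane, so they
are invariant to a positive rescaling of (weights, bias).  Sign convention
throughout: positive = background (cell-free), negative = cellular.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from skimage.filters import threshold_otsu

from .image import CalibratedImage, InputError
from .patches import (FeatureConfig, PatchFeatureSets, build_patch_grid,
                      extract_feature_sets, patch_labels_from_mask)

FORMAT_VERSION = 1


class TrainingError(ValueError):
    """Raised when the training data cannot support model fitting."""


class ModelCompatibilityError(ValueError):
    """Raised when features do not match the model's configuration."""


@dataclass
class LinearModel:
    """A linear decision function scored as a signed hyperplane distance."""

    weights: np.ndarray
    bias: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        norm = float(np.linalg.norm(self.weights))
        if norm == 0:
            raise InputError("all-zero weight vector is not a valid hyperplane")

    def signed_distance(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, float) @ self.weights + self.bias) / np.linalg.norm(self.weights)


@dataclass
class Standardizer:
    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "Standardizer":
        sd = x.std(axis=0)
        return cls(x.mean(axis=0), np.where(sd > 1e-12, sd, 1.0))

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, float) - self.mean) / self.scale


def _fit_linear_svm(x: np.ndarray, y: np.ndarray, C: float,
                    class_weight: str | None = None) -> LinearModel:
    if len(np.unique(y)) < 2:
        raise TrainingError(
            "training patches contain a single class; provide images with both "
            "cellular and background regions")
    svm = SVC(kernel="linear", C=C, class_weight=class_weight)
    svm.fit(x, y.astype(int))
    return LinearModel(svm.coef_[0].copy(), float(svm.intercept_[0]))


def threshold_confidence(confidence: np.ndarray, method: str = "otsu") -> np.ndarray:
    """Binarize a confidence map into patch labels (True = background).

    ``svm-zero`` uses the SVM's native decision boundary (score > 0).
    ``otsu`` picks the threshold by Otsu's criterion on the score histogram —
    the automatic choice for images whose score distribution is bimodal —
    but clamps to 0 when the scores are single-class (all of one sign with a
    dip-free histogram), where Otsu would split a unimodal cluster in half.
    """
    scores = np.asarray(confidence, float)
    if method == "svm-zero":
        return scores > 0
    if method != "otsu":
        raise InputError(f"unknown threshold method {method!r}")
    flat = scores.ravel()
    if flat.max() == flat.min():
        return scores > 0
    same_sign = flat.min() >= 0 or flat.max() <= 0
    if same_sign and _is_unimodal(flat):
        return scores > 0
    return scores > threshold_otsu(flat, nbins=64)


def _is_unimodal(values: np.ndarray, nbins: int = 16) -> bool:
    """Dip-free check: the kernel-smoothed score histogram rises to a single
    peak then falls.  Dips below 2% of the peak are sampling noise, not a
    second mode."""
    from scipy.ndimage import gaussian_filter1d

    hist, _ = np.histogram(values, bins=nbins)
    smooth = gaussian_filter1d(hist.astype(float), 1.5, mode="nearest")
    tol = 0.02 * smooth.max()
    peak = int(np.argmax(smooth))
    rising = np.all(np.diff(smooth[: peak + 1]) >= -tol)
    falling = np.all(np.diff(smooth[peak:]) <= tol)
    return bool(rising and falling)


class CascadePatchClassifier(BaseEstimator):
    """Patch-level background/cellular classifier (SVM cascade).

    Parameters
    ----------
    patch_size : int, default 20
        Side of the square patches in pixels.
    C : float, default 1.0
        SVM regularization for stage-one models and the combiner.
    feature_config : FeatureConfig
        Definition of the per-patch feature sets.
    background_majority : float, default 0.5
        A training patch is labeled background iff more than this fraction
        of its pixels are background in the truth mask.
    threshold_method : {"otsu", "svm-zero"}, default "otsu"
        Automatic threshold applied by :meth:`predict`.
    class_weight : None or "balanced", default None
        Hinge-loss class weighting.  Unweighted training places the decision
        boundary so that mixed boundary patches split evenly, which keeps
        the segmented wound area unbiased; "balanced" trades that for recall
        of the background class under extreme imbalance.
    random_state : int, default 0
        Seed for the cross-fitting fold split; training is deterministic
        given the data and this seed.

    Attributes
    ----------
    scalers_ : list of Standardizer, one per feature set
    stage_models_ : list of LinearModel, one per feature set
    combiner_scaler_ : Standardizer over the stage-one score vector
    combiner_ : LinearModel over standardized stage-one scores
    """

    def __init__(self, patch_size: int = 20, C: float = 1.0,
                 feature_config: FeatureConfig = FeatureConfig(),
                 background_majority: float = 0.5,
                 threshold_method: str = "otsu",
                 class_weight: str | None = None, random_state: int = 0):
        self.patch_size = patch_size
        self.C = C
        self.feature_config = feature_config
        self.background_majority = background_majority
        self.threshold_method = threshold_method
        self.class_weight = class_weight
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def collect_training_patches(self, images: list[CalibratedImage],
                                 masks: list[np.ndarray]) -> tuple[list[np.ndarray], np.ndarray]:
        """Feature blocks (one per set) and patch labels pooled over images."""
        blocks: list[list[np.ndarray]] = None
        labels = []
        for image, mask in zip(images, masks):
            if image.shape != np.asarray(mask).shape:
                raise InputError("training mask not aligned to its image")
            grid = build_patch_grid(image, self.patch_size)
            feats = extract_feature_sets(image, grid, self.feature_config)
            if blocks is None:
                blocks = [[] for _ in feats.sets]
            for k, block in enumerate(feats.sets):
                blocks[k].append(block)
            labels.append(patch_labels_from_mask(mask, grid,
                                                 self.background_majority).ravel())
        return [np.vstack(b) for b in blocks], np.concatenate(labels)

    def fit(self, images: list[CalibratedImage], masks: list[np.ndarray]):
        """Train the cascade from images with aligned truth masks."""
        blocks, y = self.collect_training_patches(images, masks)
        self.fit_patches(blocks, y)
        return self

    def fit_patches(self, blocks: list[np.ndarray], y: np.ndarray):
        """Train from precomputed per-set feature blocks and patch labels."""
        y = np.asarray(y, bool)
        if len(np.unique(y)) < 2:
            raise TrainingError(
                "training data contains a single patch class; cannot train")
        self.scalers_ = [Standardizer.fit(b) for b in blocks]
        std_blocks = [s.transform(b) for s, b in zip(self.scalers_, blocks)]

        # out-of-fold stage-one scores for cross-fitted stacking
        oof = np.zeros((len(y), len(blocks)))
        skf = StratifiedKFold(n_splits=2, shuffle=True,
                              random_state=self.random_state)
        for train_idx, test_idx in skf.split(std_blocks[0], y):
            for k, b in enumerate(std_blocks):
                fold_model = _fit_linear_svm(b[train_idx], y[train_idx], self.C,
                                             self.class_weight)
                oof[test_idx, k] = fold_model.signed_distance(b[test_idx])

        self.stage_models_ = [_fit_linear_svm(b, y, self.C, self.class_weight)
                              for b in std_blocks]
        self.combiner_scaler_ = Standardizer.fit(oof)
        self.combiner_ = _fit_linear_svm(self.combiner_scaler_.transform(oof), y,
                                         self.C, self.class_weight)
        return self

    # -------------------------------------------------------------- scoring

    def _check_features(self, features: PatchFeatureSets) -> None:
        expected = self.feature_config.lengths
        got = tuple(b.shape[1] for b in features.sets)
        if got != expected:
            raise ModelCompatibilityError(
                f"feature lengths {got} do not match model configuration {expected}")

    def stage_scores(self, features: PatchFeatureSets) -> np.ndarray:
        """(n_patches, n_sets) signed distances of the stage-one SVMs."""
        self._check_features(features)
        return np.column_stack([
            m.signed_distance(s.transform(b))
            for m, s, b in zip(self.stage_models_, self.scalers_, features.sets)])

    def score_features(self, features: PatchFeatureSets) -> np.ndarray:
        """Grid-shaped confidence map (positive = background) from features."""
        z = self.combiner_scaler_.transform(self.stage_scores(features))
        scores = self.combiner_.signed_distance(z)
        g = features.grid
        return scores.reshape(g.n_rows, g.n_cols)

    def decision_function(self, image: CalibratedImage) -> np.ndarray:
        """Confidence map of an image on its patch grid."""
        grid = build_patch_grid(image, self.patch_size)
        return self.score_features(extract_feature_sets(image, grid, self.feature_config))

    def predict(self, image: CalibratedImage) -> np.ndarray:
        """Patch labels (True = background) after automatic thresholding."""
        return threshold_confidence(self.decision_function(image),
                                    self.threshold_method)

    # -------------------------------------------------------- serialization

    def to_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "kind": "cascade",
            "patch_size": self.patch_size,
            "C": self.C,
            "background_majority": self.background_majority,
            "threshold_method": self.threshold_method,
            "class_weight": self.class_weight,
            "random_state": self.random_state,
            "feature_config": {
                "intensity_bins": self.feature_config.intensity_bins,
                "gradient_bins": self.feature_config.gradient_bins,
                "orientation_bins": self.feature_config.orientation_bins,
                "smoothing_sigmas": list(self.feature_config.smoothing_sigmas),
            },
            "scalers": [{"mean": s.mean.tolist(), "scale": s.scale.tolist()}
                        for s in self.scalers_],
            "stage_models": [{"weights": m.weights.tolist(), "bias": m.bias}
                             for m in self.stage_models_],
            "combiner_scaler": {"mean": self.combiner_scaler_.mean.tolist(),
                                "scale": self.combiner_scaler_.scale.tolist()},
            "combiner": {"weights": self.combiner_.weights.tolist(),
                         "bias": self.combiner_.bias},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CascadePatchClassifier":
        if d.get("kind") != "cascade":
            raise ModelCompatibilityError("not a cascade model file")
        if d.get("format_version") != FORMAT_VERSION:
            raise ModelCompatibilityError(
                f"unsupported model format version {d.get('format_version')!r}")
        fc = d["feature_config"]
        model = cls(patch_size=d["patch_size"], C=d["C"],
                    feature_config=FeatureConfig(
                        intensity_bins=fc["intensity_bins"],
                        gradient_bins=fc["gradient_bins"],
                        orientation_bins=fc["orientation_bins"],
                        smoothing_sigmas=tuple(fc["smoothing_sigmas"])),
                    background_majority=d["background_majority"],
                    threshold_method=d["threshold_method"],
                    class_weight=d.get("class_weight"),
                    random_state=d["random_state"])
        model.scalers_ = [Standardizer(np.array(s["mean"]), np.array(s["scale"]))
                          for s in d["scalers"]]
        model.stage_models_ = [LinearModel(np.array(m["weights"]), m["bias"])
                               for m in d["stage_models"]]
        cs = d["combiner_scaler"]
        model.combiner_scaler_ = Standardizer(np.array(cs["mean"]), np.array(cs["scale"]))
        model.combiner_ = LinearModel(np.array(d["combiner"]["weights"]),
                                      d["combiner"]["bias"])
        return model

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "CascadePatchClassifier":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ----------------------------------------------------------- thin functions


def train_cascade(training_pairs, patch_size: int = 20,
                  seed: int = 0, **kwargs) -> CascadePatchClassifier:
    """Train a cascade from (image, truth-mask) pairs."""
    model = CascadePatchClassifier(patch_size=patch_size, random_state=seed, **kwargs)
    return model.fit([p.image for p in training_pairs], [p.mask for p in training_pairs])


def score_patches(model: CascadePatchClassifier,
                  features: PatchFeatureSets) -> np.ndarray:
    """Confidence map from precomputed features."""
    return model.score_features(features)
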