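"""Texture-based scatter-assay scoring.

Scattered colonies (dissociated, motile cells) and non-scattered colonies
(compact epithelial sheets) differ in their multi-cellular texture.  Each
image is reduced to a 10-bin descriptor: the L1-normalized histogram of
rotation-invariant uniform local binary patterns (LBP, P = 8 neighbors at
radius 1 — the only standard LBP variant with exactly 10 codes) over all
pixels segmented as cellular, after resampling the image to a common
physical resolution of 5 um/px so the descriptor compares texture at the
same physical scale across microscopes.  Bins 0..8 are uniform patterns
with that many "1" bits; bin 9 collects non-uniform patterns.  A linear SVM
on the descriptor (or on the reduced bin subset {6, 7, 9}) separates the
two phenotypes; leave-one-out and constrained split-resampling validation
quantify how well.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.feature import local_binary_pattern
from skimage.measure import block_reduce
from skimage.transform import resize
from sklearn.base import BaseEstimator, ClassifierMixin

from .cascade import (FORMAT_VERSION, LinearModel, ModelCompatibilityError,
                      Standardizer, TrainingError, _fit_linear_svm)
from .image import CalibratedImage, InputError

#: physical resolution at which scatter texture is measured
TARGET_UM_PER_PX = 5.0
#: the empirically most discriminative descriptor bins
DEFAULT_REDUCED_BINS = (6, 7, 9)


class DescriptorError(ValueError):
    """Raised when a descriptor cannot be computed (e.g. empty mask)."""


class ValidationError(ValueError):
    """Raised when a validation protocol's constraints cannot be met."""


def resample_to_target(image: CalibratedImage,
                       target_um_per_px: float = TARGET_UM_PER_PX) -> CalibratedImage:
    """Downsample to the target physical resolution.

    Local-mean block reduction by the nearest integer factor, then a bilinear
    resize for any remaining non-integer adjustment.  Upsampling is refused:
    texture cannot be invented.
    """
    ratio = target_um_per_px / image.pixel_size_um
    if ratio < 1 - 1e-9:
        raise InputError("image is already coarser than the target resolution")
    factor = max(1, int(round(ratio)))
    arr = image.intensities
    h, w = arr.shape
    if factor > 1:
        arr = block_reduce(arr[: h - h % factor, : w - w % factor],
                           (factor, factor), np.mean)
    remaining = ratio / factor
    if abs(remaining - 1.0) > 1e-9:
        new_shape = (max(1, int(round(arr.shape[0] / remaining))),
                     max(1, int(round(arr.shape[1] / remaining))))
        arr = resize(arr, new_shape, order=1, mode="edge", anti_aliasing=False)
    return CalibratedImage(np.clip(arr, 0, 1), target_um_per_px)


def lbp_code(neighborhood: np.ndarray) -> int:
    """Rotation-invariant uniform LBP code (0..9) of one 3x3 neighborhood.

    The 8 samples lie on the unit circle around the center; diagonal sample
    points are bilinearly interpolated.  Ties (neighbor == center) count as
    1.  Uniform patterns (<= 2 circular 0/1 transitions) map to their count
    of ones; all others map to 9.
    """
    nb = np.asarray(neighborhood, float)
    if nb.shape != (3, 3):
        raise InputError("neighborhood must be 3x3")
    center = nb[1, 1]
    d = 1.0 / np.sqrt(2.0)
    samples = []
    for angle in np.arange(8) * (np.pi / 4.0):
        ry, rx = np.sin(angle), np.cos(angle)
        y, x = 1.0 + ry, 1.0 + rx
        y0, x0 = int(np.floor(y)), int(np.floor(x))
        fy, fx = y - y0, x - x0
        y1, x1 = min(y0 + 1, 2), min(x0 + 1, 2)
        val = (nb[y0, x0] * (1 - fy) * (1 - fx) + nb[y0, x1] * (1 - fy) * fx
               + nb[y1, x0] * fy * (1 - fx) + nb[y1, x1] * fy * fx)
        samples.append(val)
    bits = [1 if s >= center else 0 for s in samples]
    transitions = sum(bits[i] != bits[(i + 1) % 8] for i in range(8))
    return sum(bits) if transitions <= 2 else 9


def scatter_descriptor(image: CalibratedImage,
                       cell_mask: np.ndarray) -> np.ndarray:
    """10-bin normalized LBP histogram over the cellular pixels of an image.

    Border pixels lacking a full neighborhood are skipped.  The descriptor
    is invariant to positive affine changes of gray scale and to axis-
    aligned rotations of the image.
    """
    mask = np.asarray(cell_mask, bool)
    if mask.shape != image.shape:
        raise InputError("mask shape must match image")
    interior = np.zeros_like(mask)
    interior[1:-1, 1:-1] = True
    sel = mask & interior
    if not sel.any():
        raise DescriptorError("no interior cellular pixels; cannot compute descriptor")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # float input is intended
        codes = local_binary_pattern(image.intensities, P=8, R=1, method="uniform")
    hist, _ = np.histogram(codes[sel], bins=np.arange(11) - 0.5)
    return hist / hist.sum()


def reduced_descriptor(descriptor: np.ndarray,
                       bins: tuple[int, ...] = DEFAULT_REDUCED_BINS) -> np.ndarray:
    """Select a subset of descriptor bins (in the order given)."""
    d = np.asarray(descriptor, float)
    bins = tuple(int(b) for b in bins)
    if any(b < 0 or b >= d.shape[-1] for b in bins):
        raise InputError("descriptor bin index out of range")
    return d[..., list(bins)]


class ScatterClassifier(BaseEstimator, ClassifierMixin):
    """Linear SVM on LBP scatter descriptors.

    Parameters
    ----------
    C : float, default 1.0
    standardize : bool, default True
        Standardize descriptor entries before the SVM.
    bins : tuple of int or None
        Restrict to a descriptor-bin subset (e.g. ``(6, 7, 9)``); None uses
        the full descriptor.

    Attributes
    ----------
    scaler_ : Standardizer
    model_ : LinearModel; positive signed distance = scattered
    """

    def __init__(self, C: float = 1.0, standardize: bool = True,
                 bins: tuple[int, ...] | None = None):
        self.C = C
        self.standardize = standardize
        self.bins = bins

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if self.bins is not None:
            X = reduced_descriptor(X, tuple(self.bins))
        return X

    def fit(self, X, y):
        X = self._prepare(X)
        y = np.asarray(y, bool)
        if len(np.unique(y)) < 2:
            raise TrainingError("need both scattered and non-scattered examples")
        if self.standardize:
            self.scaler_ = Standardizer.fit(X)
            X = self.scaler_.transform(X)
        else:
            self.scaler_ = Standardizer(np.zeros(X.shape[1]), np.ones(X.shape[1]))
        self.model_ = _fit_linear_svm(X, y, self.C)
        self.classes_ = np.array([False, True])
        return self

    def decision_function(self, X) -> np.ndarray:
        X = self._prepare(X)
        if X.shape[1] != len(self.scaler_.mean):
            raise ModelCompatibilityError("descriptor length mismatch")
        return self.model_.signed_distance(self.scaler_.transform(X))

    def predict(self, X) -> np.ndarray:
        """True = scattered, at the default confidence threshold 0."""
        return self.decision_function(X) > 0

    def to_dict(self) -> dict:
        return {"format_version": FORMAT_VERSION, "kind": "scatter",
                "C": self.C, "standardize": self.standardize,
                "bins": list(self.bins) if self.bins is not None else None,
                "scaler": {"mean": self.scaler_.mean.tolist(),
                           "scale": self.scaler_.scale.tolist()},
                "model": {"weights": self.model_.weights.tolist(),
                          "bias": self.model_.bias}}

    @classmethod
    def from_dict(cls, d: dict) -> "ScatterClassifier":
        if d.get("kind") != "scatter":
            raise ModelCompatibilityError("not a scatter model file")
        obj = cls(C=d["C"], standardize=d["standardize"],
                  bins=tuple(d["bins"]) if d["bins"] is not None else None)
        obj.scaler_ = Standardizer(np.array(d["scaler"]["mean"]),
                                   np.array(d["scaler"]["scale"]))
        obj.model_ = LinearModel(np.array(d["model"]["weights"]), d["model"]["bias"])
        obj.classes_ = np.array([False, True])
        return obj

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ScatterClassifier":
        return cls.from_dict(json.loads(Path(path).read_text()))


def loo_classify(descriptors, labels, seed: int = 0,
                 **clf_params) -> pd.DataFrame:
    """Leave-one-out validation: each image scored by a classifier trained
    on all others.  Returns per-image confidence and prediction at the
    default threshold 0."""
    X = np.atleast_2d(np.asarray(descriptors, float))
    y = np.asarray(labels, bool)
    if min(y.sum(), (~y).sum()) < 2:
        raise ValidationError("need at least 2 images per class")
    rows = []
    for i in range(len(y)):
        keep = np.ones(len(y), bool)
        keep[i] = False
        clf = ScatterClassifier(**clf_params).fit(X[keep], y[keep])
        conf = float(clf.decision_function(X[i: i + 1])[0])
        rows.append({"image": i, "label": bool(y[i]), "confidence": conf,
                     "predicted": conf > 0})
    return pd.DataFrame(rows)


def split_validate(descriptors, labels, n_repeats: int = 100,
                   min_minority_train: int = 3, seed: int = 0,
                   **clf_params) -> np.ndarray:
    """Repeated equal-size random splits with a minority-class constraint.

    Each repeat partitions the images into equal train/test halves and
    requires strictly more than ``min_minority_train`` minority-class images
    in the training half; a classifier is trained on the training half and
    its accuracy on the test half recorded.  Returns the accuracy of each of
    the ``n_repeats`` splits.
    """
    X = np.atleast_2d(np.asarray(descriptors, float))
    y = np.asarray(labels, bool)
    n = len(y)
    n_train = n // 2
    minority = min(y.sum(), (~y).sum())
    required = min_minority_train + 1
    if minority < required + 1 or n_train < required:
        raise ValidationError(
            f"cannot place > {min_minority_train} minority images in training "
            "while keeping at least one for testing")
    minority_label = bool(y.sum() <= (~y).sum())
    rng = np.random.default_rng(seed)
    accuracies = np.empty(n_repeats)
    for rep in range(n_repeats):
        for _ in range(10_000):
            perm = rng.permutation(n)
            train = perm[:n_train]
            n_minor = (y[train] == minority_label).sum()
            if n_minor > min_minority_train and n_minor < n_train:
                break
        else:  # pragma: no cover - constraint checked feasible above
            raise ValidationError("could not draw a split honoring the constraint")
        test = perm[n_train:]
        clf = ScatterClassifier(**clf_params).fit(X[train], y[train])
        accuracies[rep] = float(np.mean(clf.predict(X[test]) == y[test]))
    return accuracies


def descriptor_table(descriptors, labels=None, names=None) -> pd.DataFrame:
    """Descriptor matrix as a flat table (one row per image)."""
    X = np.atleast_2d(np.asarray(descriptors, float))
    df = pd.DataFrame(X, columns=[f"lbp_{i}" for i in range(X.shape[1])])
    if names is not None:
        df.insert(0, "image", names)
    if labels is not None:
        df["scattered"] = np.asarray(labels, bool)
    return df
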