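"""Patch grid construction and per-patch texture features.

The segmentation unit is a square patch (default 20x20 px).  The image is
reflect-padded on the bottom/right to the next multiple of the patch size so
that narrow marginal wound regions are kept, then tiled exactly — half-open
windows, 0-based row-major indices.

Five feature sets are extracted per patch, covering the texture families
that discriminate multi-cellular from cell-free regions in transmitted-light
images:

F1  16-bin intensity histogram on [0, 1]
F2  16-bin gradient-magnitude histogram (central differences), bins on
    [0, sqrt(2)/2] (the largest magnitude a unit-range image can produce)
F3  8-bin gradient-orientation histogram weighted by magnitude
F4  multi-scale variation: sample SD of the patch after Gaussian smoothing
    at sigma in {0, 1, 2, 4} px
F5  edge/energy pair: fraction of pixels whose gradient magnitude exceeds
    the image-global Otsu level of gradient magnitudes, and the mean
    absolute Laplacian

Histogram features are L1-normalized; all bin edges are fixed so features
are comparable across images.  The feature configuration is a parameter of
:class:`FeatureConfig` so alternative sets can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, laplace
from skimage.filters import threshold_otsu

from .image import CalibratedImage, InputError

#: largest central-difference gradient magnitude for intensities in [0, 1]
MAX_GRADIENT = np.sqrt(2.0) / 2.0


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-extraction parameters (defaults define the standard set)."""

    intensity_bins: int = 16
    gradient_bins: int = 16
    orientation_bins: int = 8
    smoothing_sigmas: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0)

    @property
    def lengths(self) -> tuple[int, ...]:
        return (self.intensity_bins, self.gradient_bins, self.orientation_bins,
                len(self.smoothing_sigmas), 2)


@dataclass(frozen=True)
class PatchGrid:
    """Exact tiling of the (padded) image by square patches."""

    patch_size: int
    n_rows: int
    n_cols: int
    image_shape: tuple[int, int]  # original, pre-padding

    @property
    def padded_shape(self) -> tuple[int, int]:
        return (self.n_rows * self.patch_size, self.n_cols * self.patch_size)

    @property
    def n_patches(self) -> int:
        return self.n_rows * self.n_cols

    def window(self, r: int, c: int) -> tuple[slice, slice]:
        s = self.patch_size
        return slice(r * s, (r + 1) * s), slice(c * s, (c + 1) * s)


def build_patch_grid(image: CalibratedImage | np.ndarray, patch_size: int = 20) -> PatchGrid:
    """Tile an image with ``patch_size`` squares, reflect-padding bottom/right
    to the next multiple where needed."""
    shape = image.shape if isinstance(image, CalibratedImage) else np.asarray(image).shape
    h, w = shape
    if patch_size < 4:
        raise InputError("patch_size must be >= 4")
    if h < 4 or w < 4:
        raise InputError("image must be at least 4x4")
    n_rows = -(-h // patch_size)
    n_cols = -(-w // patch_size)
    return PatchGrid(patch_size, n_rows, n_cols, (h, w))


def pad_to_grid(arr: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """Reflect-pad an image or mask on the bottom/right to the grid's shape."""
    ph, pw = grid.padded_shape
    h, w = arr.shape
    if (h, w) == (ph, pw):
        return arr
    return np.pad(arr, ((0, ph - h), (0, pw - w)), mode="reflect")


@dataclass(frozen=True)
class PatchFeatureSets:
    """Per-patch feature vectors, one 2-D block per feature set.

    ``sets[k]`` has shape (n_patches, len_k), rows in grid row-major order.
    """

    grid: PatchGrid
    sets: tuple[np.ndarray, ...]
    config: FeatureConfig

    @property
    def stacked(self) -> np.ndarray:
        return np.hstack(self.sets)

    def to_frame(self, image_id: str = "") -> pd.DataFrame:
        """Flat table (image-id, r, c, F1..F5 concatenated) for export."""
        rows, cols = np.divmod(np.arange(self.grid.n_patches), self.grid.n_cols)
        cols_names = [f"f{k + 1}_{j}" for k, block in enumerate(self.sets)
                      for j in range(block.shape[1])]
        df = pd.DataFrame(self.stacked, columns=cols_names)
        df.insert(0, "c", cols)
        df.insert(0, "r", rows)
        df.insert(0, "image_id", image_id)
        return df


def _normalized_hist(values: np.ndarray, weights: np.ndarray | None,
                     bins: int, lo: float, hi: float) -> np.ndarray:
    hist, _ = np.histogram(values, bins=bins, range=(lo, hi), weights=weights)
    total = hist.sum()
    if total <= 0:
        return np.full(bins, 1.0 / bins)
    return hist / total


def extract_feature_sets(image: CalibratedImage, grid: PatchGrid,
                         config: FeatureConfig = FeatureConfig()) -> PatchFeatureSets:
    """Extract the five feature sets for every patch of ``grid``.

    Gradients, smoothing and the Laplacian are evaluated per patch (reflect
    boundaries), so a constant patch yields exactly zero texture response
    regardless of its surroundings.  The Otsu edge level for F5 is global:
    it is computed once from the pooled per-patch gradient magnitudes of the
    whole image.
    """
    if grid.image_shape != image.shape:
        raise InputError("grid was not built from this image")
    arr = pad_to_grid(image.intensities, grid)
    s = grid.patch_size
    n = grid.n_patches

    f1 = np.empty((n, config.intensity_bins))
    f2 = np.empty((n, config.gradient_bins))
    f3 = np.empty((n, config.orientation_bins))
    f4 = np.empty((n, len(config.smoothing_sigmas)))
    f5 = np.empty((n, 2))

    grad_mags, grad_angles, laplacians = [], [], []
    patches = (arr.reshape(grid.n_rows, s, grid.n_cols, s)
               .transpose(0, 2, 1, 3).reshape(n, s, s))
    for i in range(n):
        patch = patches[i]
        gy, gx = np.gradient(patch)
        mag = np.hypot(gx, gy)
        grad_mags.append(mag)
        grad_angles.append(np.arctan2(gy, gx))
        laplacians.append(laplace(patch, mode="reflect"))

    pooled = np.concatenate([m.ravel() for m in grad_mags])
    if pooled.max() > pooled.min():
        edge_level = threshold_otsu(pooled, nbins=256)
    else:
        edge_level = float(pooled.max())  # constant image: no edges

    for i in range(n):
        patch, mag, ang = patches[i], grad_mags[i], grad_angles[i]
        f1[i] = _normalized_hist(patch.ravel(), None, config.intensity_bins, 0.0, 1.0)
        f2[i] = _normalized_hist(mag.ravel(), None, config.gradient_bins, 0.0, MAX_GRADIENT)
        f3[i] = _normalized_hist(ang.ravel(), mag.ravel(), config.orientation_bins,
                                 -np.pi, np.pi)
        for j, sigma in enumerate(config.smoothing_sigmas):
            sm = patch if sigma == 0 else gaussian_filter(patch, sigma, mode="reflect")
            f4[i, j] = sm.std(ddof=1)
        f5[i, 0] = np.mean(mag > edge_level)
        f5[i, 1] = np.mean(np.abs(laplacians[i]))

    sets = (f1, f2, f3, f4, f5)
    for block in sets:
        if not np.all(np.isfinite(block)):
            raise InputError("non-finite feature values")
    return PatchFeatureSets(grid, sets, config)


def patch_labels_from_mask(mask: np.ndarray, grid: PatchGrid,
                           background_majority: float = 0.5) -> np.ndarray:
    """Patch-level labels from a pixel truth mask: a patch is background iff
    more than ``background_majority`` of its pixels are background.

    Returns a bool array of shape (n_rows, n_cols), True = background.
    """
    padded = pad_to_grid(np.asarray(mask, bool), grid)
    s = grid.patch_size
    frac = (padded.reshape(grid.n_rows, s, grid.n_cols, s)
            .mean(axis=(1, 3)))
    return frac > background_majority


def labels_to_pixels(labels: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """Expand patch-level labels (or scores) to pixel resolution by
    nearest-neighbor replication within each patch window, cropped to the
    original image shape."""
    s = grid.patch_size
    full = np.repeat(np.repeat(labels, s, axis=0), s, axis=1)
    h, w = grid.image_shape
    return full[:h, :w]
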