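"""Calibrated grayscale images and mask I/O.

A :class:`CalibratedImage` is the universal input of the pipeline: a 2-D
float array of intensities normalized to [0, 1] together with the physical
pixel size in micrometres per pixel.  Binary segmentation masks use the
convention ``True``/255 = background (cell-free) and ``False``/0 = cellular,
matching the sign convention of the patch classifier's confidence scores
(positive = background).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile


class InputError(ValueError):
    """Raised for invalid inputs (shape mismatches, bad parameters)."""


@dataclass(frozen=True)
class CalibratedImage:
    """2-D grayscale image with known pixel size.

    Parameters
    ----------
    intensities : ndarray of float, shape (H, W)
        Grayscale values normalized to [0, 1].
    pixel_size_um : float
        Physical pixel size in micrometres per pixel; must be positive.
    """

    intensities: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 2:
            raise InputError(f"expected a 2-D grayscale array, got ndim={arr.ndim}")
        if not np.all(np.isfinite(arr)):
            raise InputError("image contains non-finite values")
        if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
            raise InputError("intensities must be normalized to [0, 1]")
        if not self.pixel_size_um > 0:
            raise InputError("pixel_size_um must be positive")
        object.__setattr__(self, "intensities", np.clip(arr, 0.0, 1.0))

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    @classmethod
    def from_array(cls, raw: np.ndarray, pixel_size_um: float) -> "CalibratedImage":
        """Build from a raw array, normalizing integer dtypes by their full range
        and min-max rescaling floats that fall outside [0, 1]."""
        raw = np.asarray(raw)
        if np.issubdtype(raw.dtype, np.integer):
            arr = raw.astype(float) / float(np.iinfo(raw.dtype).max)
        else:
            arr = raw.astype(float)
            lo, hi = float(arr.min()), float(arr.max())
            if lo < 0 or hi > 1:
                arr = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
        return cls(arr, pixel_size_um)


def read_image(path: str | Path, pixel_size_um: float) -> CalibratedImage:
    """Read an 8/16-bit grayscale TIFF or PNG as a calibrated image."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        raw = tifffile.imread(path)
    else:
        raw = iio.imread(path)
    if raw.ndim == 3:  # collapse trivial channel axes
        raw = raw[..., 0]
    return CalibratedImage.from_array(raw, pixel_size_um)


def write_image(path: str | Path, image: CalibratedImage, bit_depth: int = 16) -> None:
    """Write as 16-bit grayscale TIFF or 8-bit PNG (quantizing [0,1] floats)."""
    path = Path(path)
    if bit_depth == 16:
        data = np.round(image.intensities * 65535).astype(np.uint16)
        if path.suffix.lower() in {".tif", ".tiff"}:
            tifffile.imwrite(path, data)
        else:
            iio.imwrite(path, data)
    elif bit_depth == 8:
        data = np.round(image.intensities * 255).astype(np.uint8)
        iio.imwrite(path, data)
    else:
        raise InputError("bit_depth must be 8 or 16")


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask PNG; nonzero pixels are background."""
    raw = iio.imread(Path(path))
    if raw.ndim == 3:
        raw = raw[..., 0]
    return raw > 0


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as 8-bit PNG with {0 = cellular, 255 = background}."""
    iio.imwrite(Path(path), np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))
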