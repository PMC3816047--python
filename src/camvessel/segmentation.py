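"""Bernsen local-contrast thresholding of smoothed CAM images.

Vessels are dark structures on a bright, unevenly illuminated yolk
background, so a single global threshold fails; Bernsen's rule thresholds
each pixel against the mid-range of its own neighbourhood, which makes the
segmentation robust to illumination gradients. Windows whose local contrast
falls below a floor are treated as featureless background rather than being
split arbitrarily at the mid-range.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .preprocess import CalibratedImage

__all__ = ["BinaryMask", "BernsenParams", "bernsen_threshold", "save_mask", "load_mask"]


@dataclass(frozen=True)
class BinaryMask:
    """Per-pixel vessel labels (1 = vessel) sharing the source calibration."""

    labels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or lab.size == 0:
            raise ValueError("labels must be a non-empty 2-D array")
        lab = lab.astype(np.uint8)
        if not np.isin(lab, (0, 1)).all():
            raise ValueError("labels must contain only 0 and 1")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "labels", lab)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def astype_bool(self) -> np.ndarray:
        return self.labels.astype(bool)

    def with_labels(self, labels: np.ndarray) -> "BinaryMask":
        return BinaryMask(labels=labels, pixel_size_um=self.pixel_size_um)


@dataclass(frozen=True)
class BernsenParams:
    """Neighbourhood radius (disk, pixels) and minimum local contrast.

    Windows with contrast (local max - local min) below ``contrast_min``
    are labelled background: the mid-range threshold is meaningless in flat
    regions and would otherwise binarise pure noise.
    """

    radius_px: int = 15
    contrast_min: float = 0.06

    def __post_init__(self) -> None:
        if not (isinstance(self.radius_px, (int, np.integer)) and self.radius_px >= 1):
            raise ValueError("radius_px must be an integer >= 1")
        if not (0.0 <= self.contrast_min <= 1.0):
            raise ValueError("contrast_min must lie in [0, 1]")


def bernsen_threshold(
    img: CalibratedImage,
    params: BernsenParams = BernsenParams(),
    invert: bool = False,
) -> BinaryMask:
    """Binarise an image with the Bernsen mid-range threshold.

    For each pixel, over the disk of ``radius_px`` (reflective borders):

        T = (local_max + local_min) / 2

    The pixel is labelled vessel (1) when the window contrast reaches
    ``contrast_min`` and the intensity lies below T (vessels are dark);
    ``invert=True`` flips the comparison for bright-on-dark inputs.
    """
    footprint = disk(params.radius_px)
    local_max = ndimage.maximum_filter(img.pixels, footprint=footprint, mode="reflect")
    local_min = ndimage.minimum_filter(img.pixels, footprint=footprint, mode="reflect")
    threshold = 0.5 * (local_max + local_min)
    contrast_ok = (local_max - local_min) >= params.contrast_min
    if invert:
        foreground = img.pixels > threshold
    else:
        foreground = img.pixels < threshold
    labels = (contrast_ok & foreground).astype(np.uint8)
    return BinaryMask(labels=labels, pixel_size_um=img.pixel_size_um)


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit image with 255 = vessel."""
    iio.imwrite(path, (mask.labels * 255).astype(np.uint8))


def load_mask(path: str | Path, pixel_size_um: float) -> BinaryMask:
    """Read an 8-bit mask image; any nonzero pixel counts as vessel."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return BinaryMask(labels=(arr > 0).astype(np.uint8), pixel_size_um=pixel_size_um)
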