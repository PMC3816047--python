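from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from camvessel import CalibratedImage, BinaryMask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_image(pixels, pixel_size_um=1.0) -> CalibratedImage:
    return CalibratedImage(pixels=np.asarray(pixels, dtype=float), pixel_size_um=pixel_size_um)


def make_mask(labels, pixel_size_um=1.0) -> BinaryMask:
    return BinaryMask(labels=np.asarray(labels, dtype=np.uint8), pixel_size_um=pixel_size_um)


def spanning_bar(height_px: int, width_px: int, bar_width_px: int, horizontal=True) -> np.ndarray:
    """A bar of the given width crossing the whole image (vessel through the field)."""
    m = np.zeros((height_px, width_px), dtype=np.uint8)
    if horizontal:
        start = (height_px - bar_width_px) // 2
        m[start : start + bar_width_px, :] = 1
    else:
        start = (width_px - bar_width_px) // 2
        m[:, start : start + bar_width_px] = 1
    return m
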