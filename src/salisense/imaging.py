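"""Colour extraction from before/after scans of the sensor.

Reimplements the manual image-analysis step: for each of the 12 spots the
mean R, G, B intensity is read inside a circular region of interest, and the
sample's signature is the 36-element vector of absolute before/after
differences of those spot means (receptor-major: S1_R, S1_G, S1_B, ...).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .layout import LayoutError, SensorLayout


class ImageError(ValueError):
    """Raised for images that do not match the expected format/layout."""


def load_image(path) -> np.ndarray:
    """Read an 8-bit RGB image into an (H, W, 3) uint8 array."""
    try:
        with Image.open(path) as img:
            arr = np.asarray(img.convert("RGB"), dtype=np.uint8)
    except (OSError, SyntaxError) as exc:
        raise ImageError(f"cannot read image {path}: {exc}") from exc
    return arr


def save_image(array: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(array, dtype=np.uint8), mode="RGB").save(Path(path))


def _check_image(image: np.ndarray, layout: SensorLayout | None = None) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ImageError(f"expected an (H, W, 3) RGB image, got shape {image.shape}")
    if layout is not None and image.shape[:2] != layout.shape:
        raise ImageError(
            f"image shape {image.shape[:2]} does not match layout {layout.shape}")
    return image.astype(float)


def extract_spot_means(image, layout: SensorLayout) -> np.ndarray:
    """(12, 3) table of mean channel intensities over each spot's disk."""
    img = _check_image(image, layout)
    means = np.empty((12, 3))
    for i, mask in enumerate(layout.masks()):
        count = int(mask.sum())
        if count == 0:
            raise LayoutError(f"spot S{i + 1} covers no pixels")
        means[i] = img[mask].mean(axis=0)
    return means


def compute_response_vector(before, after, layout: SensorLayout) -> np.ndarray:
    """36-element |after - before| vector of spot-mean colour differences."""
    mb = extract_spot_means(before, layout)
    ma = extract_spot_means(after, layout)
    return np.abs(ma - mb).reshape(36)


def make_color_map(before, after) -> np.ndarray:
    """Per-pixel absolute difference image (uint8) for visual QC."""
    b = _check_image(before)
    a = _check_image(after)
    if a.shape != b.shape:
        raise ImageError(f"image shapes differ: {b.shape} vs {a.shape}")
    return np.abs(a - b).round().clip(0, 255).astype(np.uint8)
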