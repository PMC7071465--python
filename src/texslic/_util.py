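"""Shared numeric helpers."""

from __future__ import annotations

import numpy as np


def round_half_up(x: np.ndarray | float) -> np.ndarray:
    """Round to nearest integer with ties going up (0.5 -> 1, 102.5 -> 103).

    numpy's ``round`` uses banker's rounding; all stages of this package
    quantize fractional gray levels with half-up rounding so that lookup
    tables and stage outputs are bit-reproducible across platforms.
    """
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


def to_uint8(x: np.ndarray) -> np.ndarray:
    """Clip to [0, 255], round half-up and cast to uint8."""
    return np.clip(round_half_up(x), 0, 255).astype(np.uint8)


def validate_gray_image(image: np.ndarray, min_size: int = 3) -> np.ndarray:
    """Validate a 2-D 8-bit gray raster and return it as a uint8 array.

    Raises ``ValueError`` for wrong dimensionality, out-of-range values or
    images smaller than ``min_size`` on either axis (the local 3x3
    neighborhood operators need at least a 3x3 raster).
    """
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D gray image, got ndim={arr.ndim}")
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.shape[0] < min_size or arr.shape[1] < min_size:
        raise ValueError(
            f"image must be at least {min_size}x{min_size}, got {arr.shape}"
        )
    if arr.dtype != np.uint8:
        if np.any((arr < 0) | (arr > 255)):
            raise ValueError("gray values must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr
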