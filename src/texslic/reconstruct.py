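"""Gray-level reconstruction via the 3-D histogram model.

Brain MR images suffer from non-uniform gray distribution (bias fields,
impulse-like acquisition artifacts).  Each pixel is summarised by the triple
``(f, g, h)`` — its own gray value, the mean of its 3x3 neighborhood and the
median of its 3x3 neighborhood.  On a clean, locally uniform image these
triples sit on the diagonal of the (f, g, h) histogram cube; corrupted
pixels fall off the diagonal and are pulled back by replacing the deviating
coordinates with robust combinations of the others.

The cube is partitioned into region *pairs* by how far ``f`` and ``g``
deviate from the median ``h`` (threshold ``theta``, in gray levels):

====== =============================== ==========================
region condition                       correction
====== =============================== ==========================
0      |f-h| <= theta, |g-h| <= theta  none (on-diagonal)
2      |f-h| >  theta, |g-h| <= theta  f* = (g + h) / 2
4      |f-h| <= theta, |g-h| >  theta  g* = (f + h) / 2
6      |f-h| >  theta, |g-h| >  theta  f* = g* = h
====== =============================== ==========================

The reconstructed pixel is ``round((f* + g* + h*) / 3)``.  The odd members
of each region pair (above vs. below the diagonal) receive the identical
correction and are therefore collapsed onto the even index.

All neighborhoods use replicate (edge) padding so border pixels keep a full
3x3 window.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ._util import round_half_up, to_uint8, validate_gray_image

__all__ = [
    "local_stats",
    "classify_region",
    "correct_triple",
    "reconstruct_image",
]

DEFAULT_THETA = 10.0
"""Default deviation threshold, in gray levels, for the region partition."""

_MEAN_KERNEL = np.ones((3, 3), dtype=np.int64)


def local_stats(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel (f, g, h): gray value, 3x3 mean and 3x3 median.

    The mean is computed as an exact integer sum divided by 9 so that
    classification thresholds are not perturbed by accumulated floating
    error.  Borders are replicate-padded.

    Returns three float64 arrays of the image's shape.
    """
    img = validate_gray_image(image)
    f = img.astype(np.float64)
    total = ndimage.correlate(img.astype(np.int64), _MEAN_KERNEL, mode="nearest")
    g = total / 9.0
    h = ndimage.median_filter(img, size=3, mode="nearest").astype(np.float64)
    return f, g, h


def classify_region(
    f: np.ndarray | float,
    g: np.ndarray | float,
    h: np.ndarray | float,
    theta: float = DEFAULT_THETA,
) -> np.ndarray:
    """Histogram-cube region index (0, 2, 4 or 6) for each (f, g, h) triple.

    ``theta`` is the deviation tolerance in gray levels; ``theta >= 0``.
    Works elementwise on arrays or scalars (scalars return a 0-d array).
    """
    if theta < 0:
        raise ValueError(f"theta must be >= 0, got {theta}")
    f = np.asarray(f, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    h = np.asarray(h, dtype=np.float64)
    df = np.abs(f - h) > theta
    dg = np.abs(g - h) > theta
    return (np.where(df, 2, 0) + np.where(dg, 4, 0)).astype(np.int64)


def correct_triple(
    f: np.ndarray | float,
    g: np.ndarray | float,
    h: np.ndarray | float,
    region: np.ndarray | int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Corrected (f*, g*, h*) given each triple's region index.

    Region 0 leaves the triple untouched; region 2 replaces the gray value
    with the mean/median average; region 4 replaces the neighborhood mean
    with the gray/median average; region 6 collapses both onto the median.
    The median itself is never modified.
    """
    f = np.asarray(f, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    h = np.asarray(h, dtype=np.float64)
    region = np.asarray(region)
    f_c = np.where(region == 2, (g + h) / 2.0, f)
    f_c = np.where(region == 6, h, f_c)
    g_c = np.where(region == 4, (f + h) / 2.0, g)
    g_c = np.where(region == 6, h, g_c)
    return f_c, g_c, h.copy()


def reconstruct_image(
    image: np.ndarray, theta: float = DEFAULT_THETA
) -> np.ndarray:
    """Reconstruct an 8-bit gray image with the 3-D histogram model.

    Every pixel's (f, g, h) triple is classified and corrected using the
    *original* image's local statistics (no in-place cascading), and the
    output is ``round((f* + g* + h*) / 3)`` clipped to [0, 255].

    A clean image — every triple within ``theta`` of the diagonal — is a
    fixed point of this operation.
    """
    f, g, h = local_stats(image)
    region = classify_region(f, g, h, theta)
    f_c, g_c, h_c = correct_triple(f, g, h, region)
    return to_uint8((f_c + g_c + h_c) / 3.0)


def _reconstruct_pixel(f: float, g: float, h: float, theta: float) -> int:
    """Scalar reference path for a single triple (used by diagnostics)."""
    region = int(classify_region(f, g, h, theta))
    f_c, g_c, h_c = correct_triple(f, g, h, region)
    return int(np.clip(round_half_up((float(f_c) + float(g_c) + float(h_c)) / 3.0), 0, 255))
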