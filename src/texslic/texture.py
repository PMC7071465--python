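"""Magnitude pattern of the local tri-directional pattern (LTriDP).

LTriDP is an LBP-family descriptor.  Beyond comparing each neighbor to the
center pixel (as LBP does), it also compares neighbors to *each other*
around the ring.  This module implements the magnitude component only: at
each of the eight ring positions two squared-difference energies are
compared —

* ``M1`` references the center: ``(g_prev - g_c)^2 + (g_next - g_c)^2``
* ``M2`` references the neighbor itself: ``(g_prev - g_i)^2 + (g_next - g_i)^2``

where ``g_prev``/``g_next`` are the circular predecessor and successor of
neighbor ``g_i`` on the ring.  Position ``i`` emits bit 1 when
``M1 >= M2`` and the eight bits assemble into one 8-bit code per pixel.

Conventions (fixed here; any consistent choice yields the same descriptor
up to a bit permutation):

* ring order: ``g_1`` is the top-left neighbor, then clockwise
  (top, top-right, right, bottom-right, bottom, bottom-left, left);
* the ring is circular, so neighbor 1's predecessor is neighbor 8;
* neighbor ``i`` carries bit weight ``2**(i-1)`` (neighbor 1 = LSB);
* borders are replicate-padded, matching the reconstruction stage;
* ties ``M1 == M2`` emit 1, so constant regions code to exactly 255.

The code depends only on gray *differences*: adding a constant to the
whole image (without clipping) leaves the texture map unchanged.
"""

from __future__ import annotations

import numpy as np

from ._util import validate_gray_image

__all__ = ["neighbor_ring", "magnitude_bits", "ltridp_code", "texture_map"]

#: (row, col) offsets of the ring, clockwise from the top-left neighbor.
RING_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1),
    (-1, 0),
    (-1, 1),
    (0, 1),
    (1, 1),
    (1, 0),
    (1, -1),
    (0, -1),
)


def neighbor_ring(image: np.ndarray, row: int, col: int) -> tuple[int, ...]:
    """The eight ring neighbors ``g_1..g_8`` of a pixel, clockwise from
    top-left, with replicate padding at the image border."""
    img = np.asarray(image)
    h, w = img.shape
    ring = []
    for dr, dc in RING_OFFSETS:
        r = min(max(row + dr, 0), h - 1)
        c = min(max(col + dc, 0), w - 1)
        ring.append(int(img[r, c]))
    return tuple(ring)


def magnitude_bits(center: int, ring: tuple[int, ...]) -> tuple[int, ...]:
    """The eight magnitude bits ``Mag(1..8)`` for one center/ring pair.

    For each ring position the center-referenced energy ``M1`` is compared
    with the neighbor-referenced energy ``M2``; ties resolve to 1.
    """
    if len(ring) != 8:
        raise ValueError("ring must have exactly 8 neighbors")
    c = int(center)
    bits = []
    for i in range(8):
        g_prev = int(ring[(i - 1) % 8])
        g_next = int(ring[(i + 1) % 8])
        g_i = int(ring[i])
        m1 = (g_prev - c) ** 2 + (g_next - c) ** 2
        m2 = (g_prev - g_i) ** 2 + (g_next - g_i) ** 2
        bits.append(1 if m1 >= m2 else 0)
    return tuple(bits)


def ltridp_code(bits: tuple[int, ...]) -> int:
    """Pack the eight magnitude bits into a code in [0, 255]; bit ``i``
    (neighbor ``i+1``) carries weight ``2**i``."""
    if len(bits) != 8:
        raise ValueError("expected 8 bits")
    return int(sum(int(b) << i for i, b in enumerate(bits)))


def texture_map(image: np.ndarray) -> np.ndarray:
    """Per-pixel LTriDP magnitude code map (uint8, image-shaped).

    Vectorized: builds the eight shifted neighbor planes from a
    replicate-padded copy and evaluates all bit comparisons with array
    arithmetic; equivalent bit-for-bit to applying :func:`neighbor_ring`,
    :func:`magnitude_bits` and :func:`ltridp_code` at every pixel.
    """
    img = validate_gray_image(image)
    h, w = img.shape
    pad = np.pad(img, 1, mode="edge").astype(np.int64)
    planes = [pad[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w] for dr, dc in RING_OFFSETS]
    center = img.astype(np.int64)
    code = np.zeros((h, w), dtype=np.uint8)
    for i in range(8):
        g_prev = planes[(i - 1) % 8]
        g_next = planes[(i + 1) % 8]
        g_i = planes[i]
        m1 = (g_prev - center) ** 2 + (g_next - center) ** 2
        m2 = (g_prev - g_i) ** 2 + (g_next - g_i) ** 2
        code |= ((m1 >= m2).astype(np.uint8)) << i
    return code
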